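"""QC chain: threshold semantics, brute-force normalization oracles,
stump calibration, and scale invariance of the full chain."""

import numpy as np
import pandas as pd
import pytest

import tmapanel as tp
from tmapanel.qc import _stump_threshold


def _pcm(gene_counts, neg_counts, hk_rows=()):
    """Build a ProbeCountMatrix from plain arrays."""
    gene_counts = np.asarray(gene_counts)
    neg_counts = np.asarray(neg_counts)
    genes = [f"g{i}" for i in range(gene_counts.shape[0])]
    negs = [f"n{i}" for i in range(neg_counts.shape[0])]
    samples = [f"s{i}" for i in range(gene_counts.shape[1])]
    counts = pd.DataFrame(
        np.vstack([gene_counts, neg_counts]), index=genes + negs, columns=samples
    )
    return tp.ProbeCountMatrix(
        counts=counts,
        probe_class=pd.Series(["gene"] * len(genes) + ["neg_ctrl"] * len(negs),
                              index=counts.index),
        housekeeping=pd.Series([i in hk_rows for i in range(len(genes))]
                               + [False] * len(negs), index=counts.index),
    )


class TestSequencingFilter:
    def test_low_total_and_low_relsd_excluded_threshold_passes(self):
        rng = np.random.default_rng(0)
        # s0: 1.4M reads (below); s1: constant probes (rel_sd 0); s2: healthy
        base = rng.integers(100, 20000, size=100).astype(float)
        healthy = base * (2.0e6 / base.sum())
        low = base * (1.4e6 / base.sum())
        const = np.full(100, 20000.0)
        genes = np.column_stack([low, const, healthy]).round().astype(int)
        pcm = _pcm(genes[:-2], genes[-2:], hk_rows=())
        kept, report = tp.sequencing_quality_filter(pcm)
        assert report["seq_pass"].tolist() == [False, False, True]
        assert kept.sample_ids == ["s2"]

    def test_bounds_are_strict(self):
        # a sample exactly at 1.5M total and rel_sd exactly >= 0.1 passes
        vals = np.array([10.0, 20.0, 30.0])
        vals = vals * (1.5e6 / vals.sum())
        pcm = _pcm(vals.reshape(3, 1)[:2], vals.reshape(3, 1)[2:])
        kept, report = tp.sequencing_quality_filter(pcm)
        assert report.loc["s0", "total_reads"] == pytest.approx(1.5e6)
        assert bool(report.loc["s0", "seq_pass"])

    def test_zero_total_sample_reported_undefined_fail(self):
        genes = np.array([[0, 10], [0, 20]])
        negs = np.array([[0, 5]])
        pcm = _pcm(genes, negs)
        _, report = tp.sequencing_quality_filter(pcm)
        assert not report.loc["s0", "seq_pass"]
        assert np.isnan(report.loc["s0", "rel_sd"])


class TestBackgroundSubtraction:
    def test_hand_examples(self):
        pcm = _pcm(np.array([[100], [10]]), np.array([[20], [40]]))
        adj = tp.subtract_background(pcm)
        assert adj.loc["g0", "s0"] == pytest.approx(70.0)  # 100 - mean(20,40)
        assert adj.loc["g1", "s0"] == 0.0  # clamped at zero

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        genes = rng.integers(0, 500, size=(50, 10))
        negs = rng.integers(0, 100, size=(5, 10))
        pcm = _pcm(genes, negs)
        adj = tp.subtract_background(pcm).to_numpy()
        for s in range(10):
            b = sum(negs[k][s] for k in range(5)) / 5.0
            for g in range(50):
                assert adj[g, s] == pytest.approx(max(genes[g][s] - b, 0.0), abs=1e-9)

    def test_requires_negative_controls(self):
        counts = pd.DataFrame([[1]], index=["g0"], columns=["s0"])
        with pytest.raises(tp.ValidationError):
            tp.ProbeCountMatrix(
                counts=counts,
                probe_class=pd.Series(["gene"], index=counts.index),
                housekeeping=pd.Series([False], index=counts.index),
            )


class TestAdjCpm:
    def test_single_gene_sample(self):
        df = pd.DataFrame([[5.0]], index=["g0"], columns=["s0"])
        assert tp.adjcpm(df).iloc[0, 0] == pytest.approx(1.0e6)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.random((20, 3)) * 100)
        doubled = df.copy()
        doubled[0] = doubled[0] * 2
        pd.testing.assert_frame_equal(tp.adjcpm(df), tp.adjcpm(doubled))

    def test_column_sums_one_million(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.random((500, 50)) * 1000)
        out = tp.adjcpm(df)
        np.testing.assert_allclose(out.sum(axis=0), 1.0e6, atol=1e-6)

    def test_zero_total_sample_is_hard_error(self):
        df = pd.DataFrame({"good": [1.0, 2.0], "empty": [0.0, 0.0]})
        with pytest.raises(ValueError, match="empty"):
            tp.adjcpm(df)


class TestUqNormalize:
    def test_pure_rescaling_removed(self):
        rng = np.random.default_rng(4)
        a = rng.random(30) * 100
        df = pd.DataFrame({"s0": a, "s1": 2 * a})
        out = tp.uq_normalize(df)
        np.testing.assert_allclose(out["s0"], out["s1"], rtol=1e-12)

    def test_identical_samples_unchanged(self):
        rng = np.random.default_rng(5)
        a = rng.random(30) * 100
        df = pd.DataFrame({f"s{i}": a for i in range(4)})
        out = tp.uq_normalize(df)
        np.testing.assert_allclose(out.to_numpy(), df.to_numpy(), rtol=1e-12)

    def test_positive_upper_quartiles_hit_common_target(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.random((500, 50)) * 1000)
        df[df < 50] = 0.0  # include zeros: UQ uses strictly positive values
        out = tp.uq_normalize(df)
        uqs = [np.quantile(out[c][out[c] > 0], 0.75) for c in out.columns]
        np.testing.assert_allclose(uqs, uqs[0], rtol=1e-9)

    def test_all_zero_sample_rejected(self):
        df = pd.DataFrame({"s0": [1.0, 2.0], "s1": [0.0, 0.0]})
        with pytest.raises(ValueError, match="s1"):
            tp.uq_normalize(df)


def test_log_transform_values():
    df = pd.DataFrame({"s": [0.0, 1.0, 1023.0]}, index=["a", "b", "c"])
    out = tp.log_transform(df).values["s"]
    assert out.tolist() == [0.0, 1.0, 10.0]
    with pytest.raises(ValueError):
        tp.log_transform(pd.DataFrame({"s": [-1.0]}))


class TestUrnaReference:
    def _samples(self, roles):
        t = pd.DataFrame(
            {"sample_role": roles, "group": ["x"] * len(roles)},
            index=[f"s{i}" for i in range(len(roles))],
        )
        return tp.SampleTable(table=t)

    def test_mean_of_replicates(self):
        expr = tp.ExpressionMatrix(
            values=pd.DataFrame({"s0": [2.0], "s1": [4.0]}, index=["g"])
        )
        samples = self._samples(["urna_control", "urna_control"])
        assert tp.urna_reference(expr, samples).loc["g"] == pytest.approx(3.0)

    def test_identical_replicates_reference_equals_any(self):
        vals = pd.DataFrame({"s0": [1.0, 5.0], "s1": [1.0, 5.0]}, index=["g1", "g2"])
        samples = self._samples(["urna_control", "urna_control"])
        ref = tp.urna_reference(tp.ExpressionMatrix(values=vals), samples)
        np.testing.assert_allclose(ref, vals["s0"])

    def test_requires_two_replicates(self):
        expr = tp.ExpressionMatrix(values=pd.DataFrame({"s0": [1.0]}, index=["g"]))
        with pytest.raises(tp.ConfigurationError):
            tp.urna_reference(expr, self._samples(["urna_control"]))

    def test_reference_clt_bound(self):
        rng = np.random.default_rng(8)
        true = rng.random(200) * 10
        sigma, n = 0.5, 25
        vals = pd.DataFrame(
            {f"u{i}": true + rng.normal(0, sigma, 200) for i in range(n)}
        ).clip(lower=0)
        samples = self._samples(["urna_control"] * n)
        vals.columns = samples.sample_ids
        ref = tp.urna_reference(tp.ExpressionMatrix(values=vals), samples)
        assert np.all(np.abs(ref.to_numpy() - vals.to_numpy().mean(axis=1)) < 1e-12)
        assert np.all(np.abs(ref.to_numpy() - true) < 4 * sigma / np.sqrt(n) + 0.1)


class TestStumpThreshold:
    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            vals = rng.normal(0, 1, 40)
            labels = vals + rng.normal(0, 0.8, 40) < -0.2
            t = _stump_threshold(vals, labels)
            # oracle: try every midpoint and both extremes
            uniq = np.unique(vals)
            cands = np.concatenate([[uniq[0]], (uniq[:-1] + uniq[1:]) / 2])
            errs = [( (vals < c) != labels).sum() for c in cands]
            assert ((vals < t) != labels).sum() == min(errs)
            best = [c for c, e in zip(cands, errs) if e == min(errs)]
            assert t == pytest.approx(min(best))  # tie -> smallest threshold

    def test_separable_labels_zero_error(self):
        vals = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        labels = np.array([True, True, True, False, False, False])
        t = _stump_threshold(vals, labels)
        assert ((vals < t) != labels).sum() == 0


class TestSampleQualityFilter:
    def test_correlation_extremes(self, small_cohort):
        _cfg, (pcm, samples, _loci, _truth) = small_cohort
        kept, seq_rep = tp.sequencing_quality_filter(pcm)
        expr = tp.normalize(kept)
        ref = tp.urna_reference(expr, samples)
        report = tp.sample_quality_filter(
            expr, ref, samples, kept.housekeeping_genes, seq_report=seq_rep
        )
        # uRNA replicates essentially reproduce their own mean profile
        urna = samples.samples_with_role("urna_control")
        assert (report.table.loc[urna, "urna_corr"] > 0.95).all()
        assert report.table.loc[urna, "quality_pass"].all()

    def test_sample_identical_and_anticorrelated_to_reference(self):
        rng = np.random.default_rng(10)
        ref = pd.Series(rng.random(100) * 10, index=[f"g{i}" for i in range(100)])
        anti = (ref.max() + ref.min()) - ref  # perfectly anti-correlated, positive
        hk = [f"g{i}" for i in range(9)]
        vals = pd.DataFrame({"same": ref, "anti": anti})
        samples = tp.SampleTable(
            table=pd.DataFrame(
                {"sample_role": ["tumor", "tumor"], "group": ["x", "x"]},
                index=["same", "anti"],
            )
        )
        report = tp.sample_quality_filter(
            tp.ExpressionMatrix(values=vals), ref, samples, hk
        )
        assert report.table.loc["same", "urna_corr"] == pytest.approx(1.0)
        assert report.table.loc["anti", "urna_corr"] == pytest.approx(-1.0)
        assert bool(report.table.loc["same", "quality_pass"])
        assert not bool(report.table.loc["anti", "quality_pass"])

    def test_wrong_housekeeping_count_rejected(self):
        vals = pd.DataFrame({"s0": [1.0], "s1": [2.0]}, index=["g0"])
        samples = tp.SampleTable(
            table=pd.DataFrame(
                {"sample_role": ["tumor", "tumor"], "group": ["x", "x"]},
                index=["s0", "s1"],
            )
        )
        with pytest.raises(tp.ConfigurationError, match="housekeeping"):
            tp.sample_quality_filter(
                tp.ExpressionMatrix(values=vals), vals["s0"], samples, ["g0"]
            )


class TestFullChain:
    def test_scale_invariance_without_background(self):
        """With zero background, multiplying one sample's raw counts by a
        constant leaves its normalized expression unchanged."""
        cfg = tp.CohortConfig(
            seed=21,
            n_genes=80,
            groups=[tp.GroupSpec("a", 10, [], 0.0)],
            n_urna_controls=2,
            n_normal_samples=0,
            background_mean=0.0,
            amplicon_genes=list(range(8)),
        )
        pcm, _, _, _ = tp.generate_cohort(cfg)
        expr1 = tp.normalize(pcm)
        scaled = pcm.counts.copy()
        scaled.iloc[:, 0] = scaled.iloc[:, 0] * 3
        pcm2 = tp.ProbeCountMatrix(
            counts=scaled, probe_class=pcm.probe_class, housekeeping=pcm.housekeeping
        )
        expr2 = tp.normalize(pcm2)
        np.testing.assert_allclose(
            expr1.values.to_numpy(), expr2.values.to_numpy(), atol=1e-9
        )

    def test_rerun_on_passing_data_removes_nothing(self, small_cohort):
        _cfg, (pcm, samples, _loci, _truth) = small_cohort
        expr, report = tp.run_qc(pcm, samples)
        kept = pcm.subset_samples(report.passing_samples)
        expr2, report2 = tp.run_qc(kept, samples)
        assert set(report2.passing_samples) == set(report.passing_samples)

    def test_planted_failures_excluded(self, small_cohort):
        _cfg, (pcm, samples, _loci, truth) = small_cohort
        _expr, report = tp.run_qc(pcm, samples)
        planted = {s for s, f in truth.qc_should_fail.items() if f != "pass"}
        excluded = set(samples.sample_ids) - set(report.passing_samples)
        assert excluded == planted
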