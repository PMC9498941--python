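"""Synthetic cohort generator.

Emulates the statistical structure of a targeted probe-panel (RNA counting)
experiment run on a pan-cancer tissue microarray:

* per-sample library-size variation around a mean sequencing depth;
* overdispersed gene counts (gamma-Poisson, shared dispersion);
* an additive, probe-independent background floor that also drives the
  negative-control probes (non-specific signal from undigested probes);
* stably expressed housekeeping genes with no group effect;
* universal-reference-RNA (uRNA) control replicates drawn around the
  background cohort profile;
* subtype-specific marker over-expression per sample group;
* an 8-gene co-amplified genomic neighborhood (anchor + 7 neighbors on one
  chromosome, mimicking an expression amplicon);
* immunohistochemistry H-scores coupled to mRNA through a saturating
  monotone map, with optional per-group decoupling (protein attenuation);
* planted QC failures: samples sequenced too shallowly and profile-scrambled
  low-quality samples.

Every draw flows from a single integer seed, so identical configurations
yield byte-identical cohorts.  Ground-truth labels for every planted effect
are emitted alongside the data for recovery tests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .containers import (
    ConfigurationError,
    GeneLocusTable,
    ProbeCountMatrix,
    SampleTable,
    SignatureSet,
)


@dataclass
class GroupSpec:
    """One tumor group: name, size, and its over-expressed marker genes."""

    name: str
    n_samples: int
    marker_genes: list[int] = field(default_factory=list)
    marker_log2fc: float = 2.0


def _default_groups() -> list[GroupSpec]:
    # Four subtype-like arms of 50 samples with 30 disjoint markers each,
    # comparable to the subtype arm sizes of a pan-cancer TMA block.
    return [
        GroupSpec("grpA", 50, list(range(0, 30)), 2.0),
        GroupSpec("grpB", 50, list(range(30, 60)), 2.0),
        GroupSpec("grpC", 50, list(range(60, 90)), 2.0),
        GroupSpec("grpD", 50, list(range(90, 120)), 2.0),
    ]


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort.

    Counts follow a gamma-Poisson model: gene ``g`` in sample ``s`` has mean
    ``abundance[g] * effect[g, s] * library_size[s]`` (abundances renormalized
    per sample so the expected library size is honored), overdispersed with a
    shared ``dispersion``; an independent Poisson background with mean
    ``background_mean`` is added to every probe, and is all that the
    negative-control probes carry.
    """

    n_genes: int = 500
    n_neg_controls: int = 10
    n_housekeeping: int = 9
    groups: list[GroupSpec] = field(default_factory=_default_groups)
    n_urna_controls: int = 5
    n_normal_samples: int = 20
    library_size_mean: float = 4.0e6
    library_size_cv: float = 0.2
    dispersion: float = 0.05
    background_mean: float = 30.0
    abundance_log2_sd: float = 2.0
    amplicon_genes: list[int] = field(default_factory=lambda: list(range(120, 128)))
    amplicon_prevalence: float = 0.0
    amplicon_log2fc: float = 2.0
    tracked_genes: list[int] = field(default_factory=list)
    hscore_noise_sd: float = 15.0
    decoupled_groups: dict[str, float] = field(default_factory=dict)
    planted_fail_read_count: list[int] = field(default_factory=list)
    planted_fail_low_quality: list[int] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        def _positive(name):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

        for name in ("n_genes", "n_neg_controls", "n_housekeeping",
                     "library_size_mean", "dispersion"):
            _positive(name)
        for name in ("n_urna_controls", "n_normal_samples", "library_size_cv",
                     "background_mean", "hscore_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.n_housekeeping >= self.n_genes:
            raise ConfigurationError("n_housekeeping must be smaller than n_genes")
        if not self.groups:
            raise ConfigurationError("groups must be non-empty")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ConfigurationError("groups: group names must be unique")
        for g in self.groups:
            if g.n_samples <= 0:
                raise ConfigurationError(f"groups: {g.name} has non-positive size")
            if any(i < 0 or i >= self.n_genes for i in g.marker_genes):
                raise ConfigurationError(
                    f"groups: marker index out of range for group {g.name}"
                )
        if len(self.amplicon_genes) != 8:
            raise ConfigurationError(
                "amplicon_genes must list exactly 8 genes (anchor + 7 neighbors)"
            )
        if any(i < 0 or i >= self.n_genes for i in self.amplicon_genes):
            raise ConfigurationError("amplicon_genes: index out of gene range")
        if not 0.0 <= self.amplicon_prevalence <= 1.0:
            raise ConfigurationError("amplicon_prevalence must be in [0, 1]")
        for name, atten in self.decoupled_groups.items():
            if name not in names:
                raise ConfigurationError(f"decoupled_groups: unknown group {name!r}")
            if not 0.0 <= atten <= 1.0:
                raise ConfigurationError(
                    f"decoupled_groups: attenuation for {name!r} outside [0, 1]"
                )
        n_total = self.n_total_samples
        for fld in ("planted_fail_read_count", "planted_fail_low_quality"):
            if any(i < 0 or i >= n_total for i in getattr(self, fld)):
                raise ConfigurationError(f"{fld}: sample index out of range")
        if any(i < 0 or i >= self.n_genes for i in self.tracked_genes):
            raise ConfigurationError("tracked_genes: index out of gene range")

    @property
    def n_tumor_samples(self) -> int:
        return sum(g.n_samples for g in self.groups)

    @property
    def n_total_samples(self) -> int:
        return self.n_tumor_samples + self.n_normal_samples + self.n_urna_controls

    @property
    def housekeeping_indices(self) -> list[int]:
        # last n_housekeeping gene indices are the stable housekeeping genes
        return list(range(self.n_genes - self.n_housekeeping, self.n_genes))


@dataclass
class GroundTruth:
    """Planted-effect labels emitted with every cohort, for recovery tests."""

    sample_group: dict[str, str]
    amplicon_status: dict[str, bool]
    qc_should_fail: dict[str, str]  # pass | seq_fail | quality_fail
    true_marker_sets: dict[str, dict[str, list[str]]]
    latent_protein: dict[str, dict[str, float]]  # gene -> sample -> latent

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))

    def true_signatures(self) -> list[SignatureSet]:
        return [
            SignatureSet(name=grp, high=sets.get("high", []), low=sets.get("low", []))
            for grp, sets in sorted(self.true_marker_sets.items())
        ]


def _gene_ids(cfg: CohortConfig) -> list[str]:
    width = max(4, len(str(cfg.n_genes)))
    return [f"G{i:0{width}d}" for i in range(cfg.n_genes)]


def _build_loci(cfg: CohortConfig, gene_ids: list[str]) -> GeneLocusTable:
    """Place the 8 amplicon genes in a tight cluster on one chromosome and
    spread every other gene far apart on the remaining chromosomes."""
    amp = list(cfg.amplicon_genes)
    anchor = amp[0]
    rows = {}
    # anchor interval ~30 kb; neighbors alternate sides within +/- 51 kb
    anchor_start = 39_690_000
    anchor_end = anchor_start + 30_000
    rows[anchor] = ("chr17", anchor_start, anchor_end)
    left = anchor_start
    right = anchor_end
    for k, gi in enumerate(amp[1:]):
        if k % 2 == 0:
            right = right + 2_000
            rows[gi] = ("chr17", right, right + 8_000)
            right += 8_000
        else:
            left = left - 2_000 - 8_000
            rows[gi] = ("chr17", left, left + 8_000)
    other_chroms = [f"chr{c}" for c in range(1, 17)]
    pos = 0
    for gi in range(cfg.n_genes):
        if gi in rows:
            continue
        chrom = other_chroms[pos % len(other_chroms)]
        start = 1_000_000 * (1 + pos // len(other_chroms))
        rows[gi] = (chrom, start, start + 20_000)
        pos += 1
    table = pd.DataFrame(
        {
            "chrom": [rows[i][0] for i in range(cfg.n_genes)],
            "start": [rows[i][1] for i in range(cfg.n_genes)],
            "end": [rows[i][2] for i in range(cfg.n_genes)],
            "strand": ["+"] * cfg.n_genes,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return GeneLocusTable(table=table)


def _hscore_from_latent(latent: np.ndarray, k_half: float, noise: np.ndarray) -> np.ndarray:
    """Saturating monotone map latent -> [0, 300] with additive read-out noise."""
    with np.errstate(invalid="ignore"):
        h = 300.0 * latent / (latent + k_half)
    return np.clip(h + noise, 0.0, 300.0)


def hscore_to_ihc(h: np.ndarray | pd.Series) -> np.ndarray:
    """Default H-score -> IHC grade bins: 0: <1, 1+: [1,100], 2+: (100,200], 3+: >200."""
    h = np.asarray(h, dtype=float)
    cat = np.zeros(h.shape, dtype=np.int64)
    cat[h >= 1] = 1
    cat[h > 100] = 2
    cat[h > 200] = 3
    return cat


def generate_cohort(
    cfg: CohortConfig,
) -> tuple[ProbeCountMatrix, SampleTable, GeneLocusTable, GroundTruth]:
    """Generate one cohort; fully reproducible from ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    gene_ids = _gene_ids(cfg)
    neg_ids = [f"NEG{i:02d}" for i in range(cfg.n_neg_controls)]
    hk_idx = np.array(cfg.housekeeping_indices)

    # sample bookkeeping: tumor groups, then normals, then uRNA replicates
    sample_ids: list[str] = []
    roles: list[str] = []
    group_of: list[str] = []
    for g in cfg.groups:
        for _ in range(g.n_samples):
            sample_ids.append(f"S{len(sample_ids):04d}")
            roles.append("tumor")
            group_of.append(g.name)
    for _ in range(cfg.n_normal_samples):
        sample_ids.append(f"S{len(sample_ids):04d}")
        roles.append("normal")
        group_of.append("normal_tissue")
    for _ in range(cfg.n_urna_controls):
        sample_ids.append(f"S{len(sample_ids):04d}")
        roles.append("urna_control")
        group_of.append("urna")
    n_samples = len(sample_ids)
    roles_arr = np.array(roles)

    # base relative abundances; housekeeping genes pinned high and stable
    log2_ab = rng.normal(0.0, cfg.abundance_log2_sd, size=cfg.n_genes)
    abundance = np.power(2.0, log2_ab)
    abundance[hk_idx] = np.quantile(abundance, 0.90)

    # per-sample multiplicative effects on top of the base profile
    effects = np.ones((cfg.n_genes, n_samples))
    col = 0
    for g in cfg.groups:
        if g.marker_genes:
            effects[np.ix_(g.marker_genes, range(col, col + g.n_samples))] *= (
                2.0**g.marker_log2fc
            )
        col += g.n_samples

    # amplicon status: tumor samples only
    amplified = np.zeros(n_samples, dtype=bool)
    tumor_mask = roles_arr == "tumor"
    if cfg.amplicon_prevalence > 0:
        amplified[tumor_mask] = (
            rng.random(tumor_mask.sum()) < cfg.amplicon_prevalence
        )
        effects[np.ix_(cfg.amplicon_genes, np.where(amplified)[0])] *= (
            2.0**cfg.amplicon_log2fc
        )

    # expected counts: renormalized per-sample composition x library size
    lib_sizes = np.full(n_samples, cfg.library_size_mean)
    if cfg.library_size_cv > 0:
        shape = 1.0 / cfg.library_size_cv**2
        lib_sizes = rng.gamma(shape, cfg.library_size_mean / shape, size=n_samples)
    composition = abundance[:, None] * effects
    composition /= composition.sum(axis=0, keepdims=True)
    mean_counts = composition * lib_sizes[None, :]

    # gamma-Poisson draw with shared dispersion
    shape = 1.0 / cfg.dispersion
    lam = rng.gamma(shape, mean_counts / shape)
    counts = rng.poisson(lam).astype(np.int64)

    # additive background on every probe; negative controls are background only
    if cfg.background_mean > 0:
        counts += rng.poisson(cfg.background_mean, size=counts.shape)
        neg_counts = rng.poisson(cfg.background_mean, size=(cfg.n_neg_controls, n_samples))
    else:
        neg_counts = np.zeros((cfg.n_neg_controls, n_samples), dtype=np.int64)

    # planted QC failures
    qc_fate = {sid: "pass" for sid in sample_ids}
    for si in cfg.planted_fail_read_count:
        total = counts[:, si].sum() + neg_counts[:, si].sum()
        p = min(1.0, 5.0e5 / max(total, 1))
        counts[:, si] = rng.binomial(counts[:, si], p)
        neg_counts[:, si] = rng.binomial(neg_counts[:, si], p)
        qc_fate[sample_ids[si]] = "seq_fail"
    for si in cfg.planted_fail_low_quality:
        if qc_fate[sample_ids[si]] != "pass":
            raise ConfigurationError(
                f"sample index {si} planted as both seq_fail and quality_fail"
            )
        counts[:, si] = rng.permutation(counts[:, si])
        counts[hk_idx, si] = np.round(0.2 * counts[hk_idx, si]).astype(np.int64)
        qc_fate[sample_ids[si]] = "quality_fail"

    # H-scores for tracked genes (tumor + normal samples)
    scored_mask = tumor_mask | (roles_arr == "normal")
    latent_protein: dict[str, dict[str, float]] = {}
    hscore_cols: dict[str, np.ndarray] = {}
    ihc_cols: dict[str, np.ndarray] = {}
    atten = np.ones(n_samples)
    for gname, a in cfg.decoupled_groups.items():
        atten[np.array(group_of) == gname] = a
    gene_totals = np.maximum(counts.sum(axis=0), 1)
    for gi in cfg.tracked_genes:
        gene = gene_ids[gi]
        # latent protein tracks the sample's realized transcript abundance
        expr = np.log2(1.0 + counts[gi, :] / gene_totals * 1.0e6)
        latent = expr * atten
        k_half = float(np.median(expr[scored_mask]))
        noise = rng.normal(0.0, cfg.hscore_noise_sd, size=n_samples)
        h = _hscore_from_latent(latent, max(k_half, 1e-9), noise)
        hscore_cols[gene] = np.where(scored_mask, h, np.nan)
        ihc_cols[gene] = hscore_to_ihc(h)
        latent_protein[gene] = {
            sample_ids[s]: float(latent[s]) for s in np.where(scored_mask)[0]
        }

    # assemble containers
    all_probe_ids = gene_ids + neg_ids
    count_df = pd.DataFrame(
        np.vstack([counts, neg_counts]),
        index=pd.Index(all_probe_ids, name="probe_id"),
        columns=sample_ids,
    )
    probe_class = pd.Series(
        ["gene"] * cfg.n_genes + ["neg_ctrl"] * cfg.n_neg_controls,
        index=count_df.index,
    )
    hk_flags = pd.Series(False, index=count_df.index)
    hk_flags.iloc[hk_idx] = True
    pcm = ProbeCountMatrix(counts=count_df, probe_class=probe_class, housekeeping=hk_flags)

    meta = pd.DataFrame(
        {"sample_role": roles, "group": group_of},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    for gene, vals in hscore_cols.items():
        meta[f"hscore_{gene}"] = np.round(vals, 4)
    for gene, vals in ihc_cols.items():
        col = np.where(scored_mask, vals.astype(float), np.nan)
        meta[f"ihc_{gene}"] = col
    samples = SampleTable(table=meta)

    loci = _build_loci(cfg, gene_ids)

    truth = GroundTruth(
        sample_group={sid: grp for sid, grp in zip(sample_ids, group_of)},
        amplicon_status={sid: bool(a) for sid, a in zip(sample_ids, amplified)},
        qc_should_fail=qc_fate,
        true_marker_sets={
            g.name: {"high": [gene_ids[i] for i in g.marker_genes], "low": []}
            for g in cfg.groups
        },
        latent_protein=latent_protein,
    )
    return pcm, samples, loci, truth


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_cohort(
    cohort: tuple[ProbeCountMatrix, SampleTable, GeneLocusTable, GroundTruth],
    out_dir,
) -> Path:
    """Write a generated cohort to ``out_dir``; returns the manifest path.

    Emits ``counts.tsv``, ``samples.tsv``, ``loci.bed`` and
    ``ground_truth.json`` plus a ``manifest.json`` listing each file with
    its SHA-256 checksum.
    """
    pcm, samples, loci, truth = cohort
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tio.write_counts(pcm, out / "counts.tsv")
    tio.write_metadata(samples, out / "samples.tsv")
    tio.write_bed(loci, out / "loci.bed")
    (out / "ground_truth.json").write_text(truth.to_json() + "\n", encoding="utf-8")
    files = ["counts.tsv", "samples.tsv", "loci.bed", "ground_truth.json"]
    manifest = {
        "files": [{"name": f, "sha256": _sha256(out / f)} for f in files],
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest_path


def read_cohort(out_dir) -> tuple[ProbeCountMatrix, SampleTable, GeneLocusTable, GroundTruth]:
    """Read back a cohort written by :func:`write_cohort`."""
    out = Path(out_dir)
    pcm = tio.read_counts(out / "counts.tsv")
    samples = tio.read_metadata(out / "samples.tsv")
    loci = tio.read_bed(out / "loci.bed")
    truth = GroundTruth.from_json((out / "ground_truth.json").read_text())
    return pcm, samples, loci, truth
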