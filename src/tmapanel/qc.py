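"""Probe-count QC and adjCPM-UQ normalization.

The processing chain, in fixed order:

1. sequencing-quality filter — drop samples with a low total read count or
   a low relative standard deviation (coefficient of variation) of probe
   counts;
2. background subtraction — per sample, subtract the mean of the
   negative-control probes from every gene probe (clamped at zero);
3. adjCPM — rescale each sample to counts-per-million over gene probes;
4. upper-quartile (UQ) normalization — divide each sample by the 75th
   percentile of its strictly positive values and restore the global scale
   (median of the per-sample upper quartiles) to reduce tissue-specific bias;
5. log transform — ``log2(x + 1)``;
6. sample-quality filter — correlate each sample against the mean
   universal-RNA (uRNA) control profile; samples with R below threshold are
   labelled low quality, and an exclusion threshold on mean housekeeping
   expression is calibrated against those labels (optimal one-dimensional
   decision stump); the final pass flag applies that threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ConfigurationError,
    ExpressionMatrix,
    ProbeCountMatrix,
    SampleTable,
)

logger = logging.getLogger(__name__)


@dataclass
class QcConfig:
    """Thresholds of the QC chain (defaults are the platform's published ones)."""

    min_total_reads: float = 1.5e6
    min_rel_sd: float = 0.1
    min_urna_corr: float = 0.4
    n_housekeeping_required: int = 9
    uq_quantile: float = 0.75
    correlation_method: str = "pearson"  # or "spearman"


@dataclass
class QcReport:
    """Per-sample QC metrics plus the calibrated housekeeping threshold."""

    table: pd.DataFrame  # index sample_id
    housekeeping_threshold: float

    @property
    def passing_samples(self) -> list[str]:
        return list(self.table.index[self.table["final_pass"]])


def sequencing_quality_filter(
    counts: ProbeCountMatrix, cfg: QcConfig | None = None
) -> tuple[ProbeCountMatrix, pd.DataFrame]:
    """Drop samples with total reads or relative SD below threshold.

    ``total_reads`` sums every probe (gene and control).  ``rel_sd`` is the
    per-sample coefficient of variation (sample SD / mean) of all probe
    counts.  Both bounds are strict: a value equal to the threshold passes.
    """
    cfg = cfg or QcConfig()
    arr = counts.counts.to_numpy(dtype=float)
    totals = arr.sum(axis=0)
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel_sd = np.where(means > 0, sds / means, np.nan)
    seq_pass = (totals >= cfg.min_total_reads) & (rel_sd >= cfg.min_rel_sd)
    seq_pass &= ~np.isnan(rel_sd)
    report = pd.DataFrame(
        {"total_reads": totals, "rel_sd": rel_sd, "seq_pass": seq_pass},
        index=counts.counts.columns,
    )
    kept_ids = list(counts.counts.columns[seq_pass])
    n_dropped = len(counts.sample_ids) - len(kept_ids)
    if n_dropped:
        logger.info("sequencing filter removed %d of %d samples",
                    n_dropped, len(counts.sample_ids))
    return counts.subset_samples(kept_ids), report


def subtract_background(counts: ProbeCountMatrix) -> pd.DataFrame:
    """Subtract each sample's mean negative-control signal from gene probes.

    Returns a float gene-by-sample frame; negative-control rows are dropped.
    Values are clamped at zero to preserve count semantics.
    """
    neg = counts.counts.loc[counts.neg_ctrl_probes]
    if neg.empty:
        raise ConfigurationError("background subtraction needs >= 1 neg_ctrl probe")
    background = neg.mean(axis=0)
    genes = counts.counts.loc[counts.gene_probes].astype(float)
    adjusted = (genes - background).clip(lower=0.0)
    return adjusted


def adjcpm(adjusted: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample to counts-per-million over gene probes."""
    totals = adjusted.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(
            f"sample(s) with zero post-subtraction total: {list(zero.index)[:5]} "
            "(should have been removed by the sequencing filter)"
        )
    return adjusted * (1.0e6 / totals)


def uq_normalize(cpm: pd.DataFrame, cfg: QcConfig | None = None) -> pd.DataFrame:
    """Upper-quartile normalization preserving the global scale.

    Each sample is divided by the ``uq_quantile`` quantile of its strictly
    positive values, then multiplied by the median of those per-sample
    quantiles so log values remain on a comparable scale.
    """
    cfg = cfg or QcConfig()
    uqs = {}
    for s in cpm.columns:
        pos = cpm[s].to_numpy()
        pos = pos[pos > 0]
        if pos.size == 0:
            raise ValueError(f"sample {s!r} has no positive values for UQ normalization")
        uqs[s] = np.quantile(pos, cfg.uq_quantile)
    uq = pd.Series(uqs)
    target = float(np.median(uq.to_numpy()))
    return cpm * (target / uq)


def log_transform(values: pd.DataFrame) -> ExpressionMatrix:
    """Elementwise ``log2(x + 1)``."""
    if (values.to_numpy() < 0).any():
        raise ValueError("log transform requires non-negative input")
    return ExpressionMatrix(values=np.log2(values + 1.0))


def normalize(counts: ProbeCountMatrix, cfg: QcConfig | None = None) -> ExpressionMatrix:
    """Background subtraction -> adjCPM -> UQ -> log2(x+1)."""
    cfg = cfg or QcConfig()
    return log_transform(uq_normalize(adjcpm(subtract_background(counts)), cfg))


def urna_reference(expr: ExpressionMatrix, samples: SampleTable) -> pd.Series:
    """Mean expression profile over the uRNA control replicates."""
    urna = [s for s in samples.samples_with_role("urna_control") if s in expr.values.columns]
    if len(urna) < 2:
        raise ConfigurationError(
            f"need >= 2 uRNA control samples to build a reference, found {len(urna)}"
        )
    return expr.values[urna].mean(axis=1)


def _stump_threshold(values: np.ndarray, is_low_quality: np.ndarray) -> float:
    """Optimal 1-D decision stump: smallest midpoint threshold t minimizing
    misclassification of ``is_low_quality`` by the rule ``value < t``."""
    order = np.argsort(values, kind="stable")
    v = values[order]
    uniq = np.unique(v)
    candidates = [uniq[0]]  # everything passes
    candidates += list((uniq[:-1] + uniq[1:]) / 2.0)
    best_t, best_err = None, None
    for t in candidates:
        pred_low = values < t
        err = int((pred_low != is_low_quality).sum())
        if best_err is None or err < best_err:
            best_t, best_err = t, err
    return float(best_t)


def sample_quality_filter(
    expr: ExpressionMatrix,
    reference: pd.Series,
    samples: SampleTable,
    housekeeping_genes: list[str],
    cfg: QcConfig | None = None,
    seq_report: pd.DataFrame | None = None,
) -> QcReport:
    """Correlation filter against the uRNA reference plus the calibrated
    housekeeping exclusion threshold.

    ``quality_pass`` records the correlation rule (R >= ``min_urna_corr``);
    ``final_pass`` applies the housekeeping stump calibrated on the
    correlation labels (and requires the sequencing filter to have passed,
    when ``seq_report`` is supplied).
    """
    cfg = cfg or QcConfig()
    hk = [g for g in housekeeping_genes if g in expr.values.index]
    if len(hk) != cfg.n_housekeeping_required:
        raise ConfigurationError(
            f"expected {cfg.n_housekeeping_required} housekeeping genes, found {len(hk)}"
        )
    vals = expr.values
    ref = reference.reindex(vals.index)
    if cfg.correlation_method == "pearson":
        corr = vals.corrwith(ref, axis=0)
    elif cfg.correlation_method == "spearman":
        corr = pd.Series(
            {s: stats.spearmanr(vals[s], ref).statistic for s in vals.columns}
        )
    else:
        raise ConfigurationError(
            f"unknown correlation method {cfg.correlation_method!r}"
        )
    low_quality = (corr < cfg.min_urna_corr).to_numpy()
    hk_mean = vals.loc[hk].mean(axis=0)
    t_star = _stump_threshold(hk_mean.to_numpy(), low_quality)
    table = pd.DataFrame(
        {
            "urna_corr": corr,
            "housekeeping_mean": hk_mean,
            "quality_pass": ~low_quality,
            "final_pass": hk_mean >= t_star,
        },
        index=vals.columns,
    )
    if seq_report is not None:
        table = seq_report.join(table, how="outer")
        for col in ("seq_pass", "quality_pass", "final_pass"):
            table[col] = table[col].map(lambda v: bool(v) if pd.notna(v) else False)
        table["final_pass"] = table["final_pass"] & table["seq_pass"]
    n_low = int(low_quality.sum())
    if n_low:
        logger.info("sample-quality filter: %d low-correlation samples, "
                    "housekeeping threshold %.4f", n_low, t_star)
    return QcReport(table=table, housekeeping_threshold=t_star)


def run_qc(
    counts: ProbeCountMatrix,
    samples: SampleTable,
    cfg: QcConfig | None = None,
) -> tuple[ExpressionMatrix, QcReport]:
    """Full chain: sequencing filter -> normalization -> sample-quality filter.

    Returns the expression matrix restricted to samples passing both filters
    and the complete per-sample QC report (every input sample has a row).
    """
    cfg = cfg or QcConfig()
    kept, seq_report = sequencing_quality_filter(counts, cfg)
    expr = normalize(kept, cfg)
    reference = urna_reference(expr, samples)
    report = sample_quality_filter(
        expr, reference, samples, kept.housekeeping_genes, cfg, seq_report=seq_report
    )
    passing = [s for s in expr.values.columns if s in report.passing_samples]
    return expr.subset_samples(passing), report
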