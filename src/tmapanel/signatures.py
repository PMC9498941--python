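"""Gene-signature scoring and molecular subtype assignment.

Expression values are standardized per gene (z-scores) over a declared
sample universe.  A signature score is the mean signed z over a marker set
(+1 for genes expected high in the subtype, -1 for genes expected low), and
each sample's molecular subtype is the signature with the maximum score.
Marker genes can be selected data-driven: a two-sided test of the target
group against a comparator at a raw p-value threshold, with the sign of the
mean difference assigning the direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ConfigurationError,
    ExpressionMatrix,
    SampleTable,
    SignatureSet,
)

logger = logging.getLogger(__name__)


@dataclass
class ZMatrix:
    """Per-gene standardized expression over a declared sample universe.

    Genes constant over the universe cannot be standardized; their rows are
    zero and they are flagged ``degenerate`` (kept so signature gene counts
    stay stable).
    """

    z: pd.DataFrame
    universe: list[str]
    degenerate: pd.Series  # per-gene bool

    @property
    def gene_ids(self) -> list[str]:
        return list(self.z.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.z.columns)


@dataclass
class MarkerSelectionConfig:
    """Settings for data-driven marker selection."""

    p_threshold: float = 0.005
    comparator: str = "other_subtypes"  # or "other_subtypes_plus_normal"
    min_abs_log2fc: float = 0.0
    test: str = "welch_t"  # or "wilcoxon"

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ConfigurationError("p_threshold must be in (0, 1)")
        if self.min_abs_log2fc < 0:
            raise ConfigurationError("min_abs_log2fc must be >= 0")
        if self.comparator not in ("other_subtypes", "other_subtypes_plus_normal"):
            raise ConfigurationError(f"unknown comparator {self.comparator!r}")
        if self.test not in ("welch_t", "wilcoxon"):
            raise ConfigurationError(f"unknown test {self.test!r}")


def zscore(expr: ExpressionMatrix, universe: list[str] | None = None) -> ZMatrix:
    """Standardize each gene to mean 0, sample SD 1 over ``universe``.

    Samples outside the universe are standardized with the universe's mean
    and SD, so scores remain comparable across held-out samples.
    """
    if universe is None:
        universe = list(expr.values.columns)
    universe = list(universe)
    missing = set(universe) - set(expr.values.columns)
    if missing:
        raise ConfigurationError(f"universe samples absent from matrix: {sorted(missing)[:5]}")
    if len(universe) < 2:
        raise ConfigurationError("z-score universe must contain >= 2 samples")
    sub = expr.values[universe]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    degenerate = sd == 0
    safe_sd = sd.mask(degenerate, 1.0)
    z = expr.values.sub(mean, axis=0).div(safe_sd, axis=0)
    z[degenerate] = 0.0
    if degenerate.any():
        logger.info("zscore: %d constant gene(s) flagged degenerate", int(degenerate.sum()))
    return ZMatrix(z=z, universe=universe, degenerate=degenerate)


def signature_score(zm: ZMatrix, sig: SignatureSet) -> pd.Series:
    """Mean signed z over the signature's genes, per sample."""
    high = [g for g in sig.high if g in zm.z.index]
    low = [g for g in sig.low if g in zm.z.index]
    missing = (set(sig.high) - set(high)) | (set(sig.low) - set(low))
    if missing:
        logger.warning(
            "signature %r: %d gene(s) absent from matrix, skipped", sig.name, len(missing)
        )
    n = len(high) + len(low)
    if n == 0:
        raise ConfigurationError(
            f"signature {sig.name!r} has no genes in the expression matrix"
        )
    total = zm.z.loc[high].sum(axis=0) - zm.z.loc[low].sum(axis=0)
    score = total / n
    score.name = sig.name
    return score


def _comparator_samples(
    samples: SampleTable, target_group: str, cfg: MarkerSelectionConfig
) -> list[str]:
    t = samples.table
    tumor = t["sample_role"] == "tumor"
    other = tumor & (t["group"] != target_group)
    if cfg.comparator == "other_subtypes_plus_normal":
        other = other | (t["sample_role"] == "normal")
    return list(t.index[other])


def select_markers(
    expr: ExpressionMatrix,
    samples: SampleTable,
    target_group: str,
    cfg: MarkerSelectionConfig | None = None,
) -> tuple[SignatureSet | None, pd.DataFrame]:
    """Select subtype-discriminating genes at a raw p-value threshold.

    Per gene, a two-sided test (Welch t by default) of the target group
    against the comparator on log2 expression; genes with
    ``p < p_threshold`` and ``|mean difference| >= min_abs_log2fc`` are
    selected, the sign of the difference assigning high vs low.  No
    multiple-testing correction is applied: the raw threshold is the
    selection rule.  Returns the signature and the full per-gene statistics.
    """
    cfg = cfg or MarkerSelectionConfig()
    t = samples.table
    target_ids = [
        s
        for s in t.index[(t["sample_role"] == "tumor") & (t["group"] == target_group)]
        if s in expr.values.columns
    ]
    comp_ids = [s for s in _comparator_samples(samples, target_group, cfg)
                if s in expr.values.columns]
    if len(target_ids) < 3:
        raise ConfigurationError(
            f"target group {target_group!r} has {len(target_ids)} samples; need >= 3"
        )
    if len(comp_ids) < 3:
        raise ConfigurationError("comparator has fewer than 3 samples")
    x = expr.values[target_ids].to_numpy()
    y = expr.values[comp_ids].to_numpy()
    diff = x.mean(axis=1) - y.mean(axis=1)
    if cfg.test == "welch_t":
        res = stats.ttest_ind(x, y, axis=1, equal_var=False)
        pvals = res.pvalue
    else:
        res = stats.mannwhitneyu(x, y, axis=1, alternative="two-sided")
        pvals = res.pvalue
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    selected = (pvals < cfg.p_threshold) & (np.abs(diff) >= cfg.min_abs_log2fc)
    genes = expr.values.index
    table = pd.DataFrame(
        {"mean_diff_log2": diff, "p_value": pvals, "selected": selected},
        index=genes,
    )
    high = list(genes[selected & (diff > 0)])
    low = list(genes[selected & (diff < 0)])
    if not high and not low:
        logger.warning("no markers selected for group %r at p < %g",
                       target_group, cfg.p_threshold)
        return None, table
    return SignatureSet(name=target_group, high=high, low=low), table


def assign_subtypes(zm: ZMatrix, signatures: list[SignatureSet]) -> pd.DataFrame:
    """Score every signature and assign each sample the argmax subtype.

    Returns a frame with one ``score_<name>`` column per signature plus
    ``assigned_subtype``, ``margin`` (best minus second-best score) and
    ``tie_flag``.  Exact ties are broken lexicographically by subtype name.
    """
    if len(signatures) < 2:
        raise ConfigurationError("subtype assignment needs >= 2 signatures")
    names = sorted(s.name for s in signatures)
    if len(set(names)) != len(names):
        raise ConfigurationError("signature names must be unique")
    scores = pd.DataFrame(
        {sig.name: signature_score(zm, sig) for sig in signatures}
    )[names]
    arr = scores.to_numpy()
    best_idx = arr.argmax(axis=1)  # argmax takes the first (lexicographic) max
    order = np.sort(arr, axis=1)
    margin = order[:, -1] - order[:, -2]
    out = scores.add_prefix("score_")
    out["assigned_subtype"] = [names[i] for i in best_idx]
    out["margin"] = margin
    out["tie_flag"] = margin == 0.0
    return out


def reannotate(
    calls: pd.DataFrame,
    samples: SampleTable,
    weak_margin: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-tabulate pathological labels against molecular calls.

    Returns the contingency table (pathology rows x molecular-call columns)
    and a per-sample reassignment list carrying the call margin; calls with
    margin below ``weak_margin`` are flagged weak.
    """
    shared = [s for s in calls.index if s in samples.table.index]
    if len(shared) != len(calls.index):
        missing = sorted(set(calls.index) - set(shared))
        raise ConfigurationError(f"samples missing from metadata: {missing[:5]}")
    pathology = samples.table.loc[shared, "group"]
    molecular = calls.loc[shared, "assigned_subtype"]
    crosstab = pd.crosstab(pathology, molecular)
    crosstab.index.name = "pathology"
    crosstab.columns.name = "molecular_call"
    detail = pd.DataFrame(
        {
            "pathology": pathology,
            "molecular_call": molecular,
            "margin": calls.loc[shared, "margin"],
            "weak_call": calls.loc[shared, "margin"] < weak_margin,
            "reassigned": pathology.to_numpy() != molecular.to_numpy(),
        },
        index=pd.Index(shared, name="sample_id"),
    )
    return crosstab, detail
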