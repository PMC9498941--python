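"""Cross-platform and mRNA-protein concordance statistics.

Three related questions:

* do two expression platforms agree per gene (Pearson r, ordinary
  least-squares slope/intercept of platform 2 on platform 1, with a bias
  flag when the slope departs from 1)?
* within each sample group, does mRNA track protein (expression vs
  immunohistochemistry H-score)?
* which groups are protein-positive by IHC grade (2+/3+), and which groups
  are discordant — high mRNA rank but low protein rank or vice versa?
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigurationError, ExpressionMatrix, SampleTable
from .simulate import hscore_to_ihc

logger = logging.getLogger(__name__)


@dataclass
class ConcordanceConfig:
    slope_delta: float = 0.25      # |slope - 1| beyond which a platform bias is flagged
    rank_gap: float = 0.3          # percentile-rank gap that defines discordance
    min_group_n: int = 3
    correlation_method: str = "pearson"  # or "spearman"


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    return float(stats.pearsonr(x, y).statistic)


def platform_concordance(
    x: ExpressionMatrix,
    y: ExpressionMatrix,
    blacklist: list[str] | None = None,
    cfg: ConcordanceConfig | None = None,
) -> pd.DataFrame:
    """Per-gene agreement between two platforms on shared samples.

    For each gene present on both platforms (minus ``blacklist``), Pearson r
    and the least-squares fit of platform ``y`` on platform ``x``.
    ``bias_flag`` is ``low_in_p2`` when the slope falls below ``1 - delta``
    (platform 2 under-reads) and ``high_in_p2`` above ``1 + delta``.
    """
    cfg = cfg or ConcordanceConfig()
    blacklist = set(blacklist or [])
    shared_samples = [s for s in x.values.columns if s in set(y.values.columns)]
    if len(shared_samples) < 3:
        raise ConfigurationError(
            f"need >= 3 shared samples, found {len(shared_samples)}"
        )
    shared_genes = [
        g for g in x.values.index if g in set(y.values.index) and g not in blacklist
    ]
    if blacklist:
        logger.info("platform concordance: %d gene(s) excluded by blacklist",
                    len(set(x.values.index) & blacklist))
    xm = x.values.loc[shared_genes, shared_samples].to_numpy()
    ym = y.values.loc[shared_genes, shared_samples].to_numpy()
    n = len(shared_samples)
    mx = xm.mean(axis=1)
    my = ym.mean(axis=1)
    xc = xm - mx[:, None]
    yc = ym - my[:, None]
    sxx = (xc * xc).sum(axis=1)
    syy = (yc * yc).sum(axis=1)
    sxy = (xc * yc).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(sxx > 0, sxy / sxx, np.nan)
        r = np.where((sxx > 0) & (syy > 0), sxy / np.sqrt(sxx * syy), np.nan)
    intercept = my - slope * mx
    flags = np.full(len(shared_genes), "none", dtype=object)
    flags[slope < 1.0 - cfg.slope_delta] = "low_in_p2"
    flags[slope > 1.0 + cfg.slope_delta] = "high_in_p2"
    out = pd.DataFrame(
        {"r": r, "slope": slope, "intercept": intercept, "n": n, "bias_flag": flags},
        index=pd.Index(shared_genes, name="gene_id"),
    )
    return out


def mrna_protein_by_group(
    expr: ExpressionMatrix,
    samples: SampleTable,
    gene: str,
    cfg: ConcordanceConfig | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-group mRNA-protein agreement for one gene.

    Returns per-group medians and within-group correlation of log2
    expression against H-score, plus the pooled all-sample correlation.
    Groups without H-scores or with fewer than ``min_group_n`` scored
    samples are skipped with a log notice.
    """
    cfg = cfg or ConcordanceConfig()
    if gene not in expr.values.index:
        raise ConfigurationError(f"gene {gene!r} absent from expression matrix")
    h = samples.hscores(gene)
    t = samples.table
    usable = [
        s
        for s in expr.values.columns
        if s in h.index and np.isfinite(h.get(s, np.nan))
        and t.loc[s, "sample_role"] in ("tumor", "normal")
    ]
    if len(usable) < cfg.min_group_n:
        raise ConfigurationError(
            f"fewer than {cfg.min_group_n} samples carry H-scores for {gene!r}"
        )
    ex = expr.values.loc[gene, usable]
    hs = h.loc[usable].astype(float)
    groups = t.loc[usable, "group"]
    rows = []
    for grp, idx in groups.groupby(groups).groups.items():
        idx = list(idx)
        if len(idx) < cfg.min_group_n:
            logger.info("group %r skipped (%d scored samples)", grp, len(idx))
            continue
        gx = ex.loc[idx].to_numpy()
        gh = hs.loc[idx].to_numpy()
        rows.append(
            {
                "group": grp,
                "n": len(idx),
                "median_mrna": float(np.median(gx)),
                "median_hscore": float(np.median(gh)),
                "r_mrna_protein": _corr(gx, gh, cfg.correlation_method),
            }
        )
    table = pd.DataFrame(rows).set_index("group")
    pooled_r = _corr(ex.to_numpy(), hs.to_numpy(), cfg.correlation_method)
    return table, pooled_r


def ihc_positivity(
    samples: SampleTable, gene: str, derive_from_hscore: bool = False
) -> pd.Series:
    """Per-group percentage of IHC-positive samples (grade 2+ or 3+).

    When no graded IHC readout exists and ``derive_from_hscore`` is set,
    grades are derived from H-scores with the default bins
    (0: <1, 1+: 1-100, 2+: >100-200, 3+: >200).  Groups are returned sorted
    by descending positivity.
    """
    t = samples.table
    col = f"ihc_{gene}"
    if col in t.columns:
        cats = t[col]
    elif derive_from_hscore and f"hscore_{gene}" in t.columns:
        h = t[f"hscore_{gene}"]
        cats = pd.Series(
            np.where(h.notna(), hscore_to_ihc(h.fillna(0)), np.nan), index=t.index
        )
        logger.info("IHC grades for %r derived from H-scores via default bins", gene)
    else:
        raise ConfigurationError(f"no IHC category data for gene {gene!r}")
    scored = cats.notna() & t["sample_role"].isin(["tumor", "normal"])
    if not scored.any():
        raise ConfigurationError(f"no graded samples for gene {gene!r}")
    sub = t.loc[scored]
    positive = cats.loc[scored].isin([2, 3])
    pct = positive.groupby(sub["group"]).mean() * 100.0
    pct.name = f"pct_ihc_positive_{gene}"
    return pct.sort_values(ascending=False)


def discordance_flags(
    group_rows: pd.DataFrame, cfg: ConcordanceConfig | None = None
) -> pd.DataFrame:
    """Flag groups whose mRNA and protein ranks disagree.

    Each group's median mRNA and median H-score are converted to percentile
    ranks in [0, 1] across groups; a gap above ``rank_gap`` in favor of mRNA
    flags ``high_mrna_low_protein`` and the converse flags
    ``low_mrna_high_protein``.
    """
    cfg = cfg or ConcordanceConfig()
    if len(group_rows) < 3:
        raise ConfigurationError("discordance ranking needs >= 3 groups")
    k = len(group_rows)
    rank_mrna = (stats.rankdata(group_rows["median_mrna"]) - 1) / (k - 1)
    rank_prot = (stats.rankdata(group_rows["median_hscore"]) - 1) / (k - 1)
    gap = rank_mrna - rank_prot
    flags = np.full(k, "none", dtype=object)
    flags[gap > cfg.rank_gap] = "high_mrna_low_protein"
    flags[gap < -cfg.rank_gap] = "low_mrna_high_protein"
    out = group_rows.copy()
    out["rank_mrna"] = rank_mrna
    out["rank_protein"] = rank_prot
    out["discordance"] = flags
    return out
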