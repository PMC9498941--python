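"""Expression-amplicon calling around an anchor gene.

Coherent over-expression of a gene and its immediate genomic neighbors is
an expression-level proxy for genomic amplification (the classic example is
ERBB2/HER2 on 17q12).  The neighborhood is every gene whose interval
overlaps a symmetric window around the anchor (default +/- 51 kb); a sample
is called amplified when its mean z-score over the neighborhood strictly
exceeds a threshold (default 1.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .containers import ConfigurationError, GeneLocusTable
from .signatures import ZMatrix


@dataclass
class AmpliconConfig:
    anchor_gene: str = "ERBB2"
    window_bp: int = 51_000
    z_threshold: float = 1.5
    include_anchor: bool = True

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ConfigurationError("window_bp must be positive")


def find_neighbors(loci: GeneLocusTable, cfg: AmpliconConfig) -> list[str]:
    """Genes overlapping the +/- window around the anchor's interval.

    The window is ``[anchor.start - window_bp, anchor.end + window_bp)`` on
    the anchor's chromosome; overlap is half-open, so a gene ending exactly
    at the window start is excluded.  Result is sorted by start coordinate
    and includes the anchor unless ``include_anchor`` is false.
    """
    t = loci.table
    if cfg.anchor_gene not in t.index:
        raise ConfigurationError(f"anchor gene {cfg.anchor_gene!r} absent from loci")
    anchor = t.loc[cfg.anchor_gene]
    win_start = anchor["start"] - cfg.window_bp
    win_end = anchor["end"] + cfg.window_bp
    same_chrom = t["chrom"] == anchor["chrom"]
    overlaps = same_chrom & (t["start"] < win_end) & (t["end"] > win_start)
    hits = t[overlaps].sort_values(["start", "end"])
    genes = list(hits.index)
    if not cfg.include_anchor:
        genes = [g for g in genes if g != cfg.anchor_gene]
    return genes


def call_amplicon(
    zm: ZMatrix, neighborhood: list[str], cfg: AmpliconConfig | None = None
) -> pd.DataFrame:
    """Flag samples whose mean neighborhood z strictly exceeds the threshold."""
    cfg = cfg or AmpliconConfig()
    if not neighborhood:
        raise ConfigurationError("empty amplicon neighborhood")
    missing = [g for g in neighborhood if g not in zm.z.index]
    if missing:
        raise ConfigurationError(f"neighborhood genes absent from z-matrix: {missing}")
    mean_z = zm.z.loc[list(neighborhood)].mean(axis=0)
    out = pd.DataFrame(
        {"mean_neighborhood_z": mean_z, "amplified": mean_z > cfg.z_threshold}
    )
    out.index.name = "sample_id"
    return out
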