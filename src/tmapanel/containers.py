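"""Validated in-memory tables shared by every analysis stage.

All containers are thin dataclasses around pandas objects.  Validation
happens at construction time so that downstream stages can assume the
invariants (unique identifiers, non-negative counts, controls present)
without re-checking them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROBE_CLASSES = ("gene", "neg_ctrl")
SAMPLE_ROLES = ("tumor", "normal", "urna_control", "multitissue_control")
STRANDS = ("+", "-", ".")


class ValidationError(ValueError):
    """Raised when a container or file violates a structural invariant."""


class ConfigurationError(ValueError):
    """Raised when a configuration object violates its invariants."""


def _check_unique(values, what: str) -> None:
    ser = pd.Series(list(values))
    if ser.duplicated().any():
        dupes = ser[ser.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class ProbeCountMatrix:
    """Raw probe-by-sample integer counts with per-probe class annotations.

    ``counts`` is indexed by probe id with one column per sample.
    ``probe_class`` labels each probe as a gene probe or a negative-control
    probe (probes with no transcript target, whose signal estimates
    non-specific background).  ``housekeeping`` flags the stably expressed
    gene probes used to calibrate the sample-quality filter.
    """

    counts: pd.DataFrame
    probe_class: pd.Series
    housekeeping: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "probe ids")
        _check_unique(self.counts.columns, "sample ids")
        if not self.probe_class.index.equals(self.counts.index):
            raise ValidationError("probe_class index does not match counts index")
        if not self.housekeeping.index.equals(self.counts.index):
            raise ValidationError("housekeeping index does not match counts index")
        bad = set(self.probe_class.unique()) - set(PROBE_CLASSES)
        if bad:
            raise ValidationError(f"unknown probe_class values: {sorted(bad)}")
        if (self.probe_class == "neg_ctrl").sum() < 1:
            raise ValidationError("at least one negative-control probe required")
        if (self.probe_class == "gene").sum() < 1:
            raise ValidationError("at least one gene probe required")
        hk_on_ctrl = self.housekeeping & (self.probe_class != "gene")
        if hk_on_ctrl.any():
            raise ValidationError(
                "housekeeping flag set on non-gene probes: "
                f"{self.counts.index[hk_on_ctrl].tolist()[:5]}"
            )
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at probe {self.counts.index[r]!r}, "
                f"sample {self.counts.columns[c]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def gene_probes(self) -> pd.Index:
        return self.counts.index[self.probe_class == "gene"]

    @property
    def neg_ctrl_probes(self) -> pd.Index:
        return self.counts.index[self.probe_class == "neg_ctrl"]

    @property
    def housekeeping_genes(self) -> list[str]:
        return list(self.counts.index[self.housekeeping])

    def subset_samples(self, sample_ids) -> "ProbeCountMatrix":
        return ProbeCountMatrix(
            counts=self.counts[list(sample_ids)],
            probe_class=self.probe_class,
            housekeeping=self.housekeeping,
        )


@dataclass
class SampleTable:
    """Per-sample metadata: role, group, optional H-scores and IHC grades.

    ``table`` is indexed by sample id.  H-score columns are named
    ``hscore_<gene>`` (values in [0, 300]); IHC grade columns are
    ``ihc_<gene>`` (integers 0-3).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample ids")
        for col in ("sample_role", "group"):
            if col not in self.table.columns:
                raise ValidationError(f"metadata missing required column {col!r}")
        bad = set(self.table["sample_role"].unique()) - set(SAMPLE_ROLES)
        if bad:
            raise ValidationError(f"unknown sample_role values: {sorted(bad)}")
        primary = self.table["sample_role"].isin(["tumor", "normal"])
        grp = self.table.loc[primary, "group"]
        if grp.isna().any() or (grp.astype(str).str.len() == 0).any():
            raise ValidationError("tumor/normal samples must carry a non-empty group")
        for col in self.hscore_columns:
            vals = self.table[col].dropna()
            if ((vals < 0) | (vals > 300)).any():
                raise ValidationError(f"{col} outside [0, 300]")
        for col in self.ihc_columns:
            vals = self.table[col].dropna()
            if not set(vals.unique()) <= {0, 1, 2, 3}:
                raise ValidationError(f"{col} has grades outside {{0,1,2,3}}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def hscore_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("hscore_")]

    @property
    def ihc_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("ihc_")]

    def samples_with_role(self, *roles: str) -> list[str]:
        mask = self.table["sample_role"].isin(roles)
        return list(self.table.index[mask])

    def hscores(self, gene: str) -> pd.Series:
        col = f"hscore_{gene}"
        if col not in self.table.columns:
            raise KeyError(f"no H-scores recorded for gene {gene!r}")
        return self.table[col]

    def ihc(self, gene: str) -> pd.Series:
        col = f"ihc_{gene}"
        if col not in self.table.columns:
            raise KeyError(f"no IHC grades recorded for gene {gene!r}")
        return self.table[col]


@dataclass
class ExpressionMatrix:
    """log2(adjCPM-UQ + 1) expression values, gene probes only."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite")
        if (arr < 0).any():
            raise ValidationError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(values=self.values[list(sample_ids)])


@dataclass
class GeneLocusTable:
    """Gene intervals (0-based, half-open) for neighborhood queries."""

    table: pd.DataFrame  # index gene_id; columns chrom, start, end, strand

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "gene ids")
        for col in ("chrom", "start", "end", "strand"):
            if col not in self.table.columns:
                raise ValidationError(f"locus table missing column {col!r}")
        bad = self.table["start"] >= self.table["end"]
        if bad.any():
            raise ValidationError(
                f"interval with start >= end for {self.table.index[bad].tolist()[:5]}"
            )
        if (self.table["start"] < 0).any():
            raise ValidationError("negative interval start")
        unknown = set(self.table["strand"].unique()) - set(STRANDS)
        if unknown:
            raise ValidationError(f"unknown strand values: {sorted(unknown)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass
class SignatureSet:
    """A named, signed marker-gene collection for one molecular subtype.

    ``high`` genes are expected to be over-expressed in the subtype and
    enter the signature score with weight +1; ``low`` genes with weight -1.
    """

    name: str
    high: list[str] = field(default_factory=list)
    low: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.high) & set(self.low)
        if overlap:
            raise ValidationError(
                f"signature {self.name!r}: genes in both directions: {sorted(overlap)[:5]}"
            )
        if not self.high and not self.low:
            raise ValidationError(f"signature {self.name!r} is empty")

    @property
    def genes(self) -> list[str]:
        return list(self.high) + list(self.low)
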