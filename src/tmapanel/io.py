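"""Readers and writers for the on-disk artifact formats.

Formats are deliberately plain text:

* counts — TSV, one row per probe: ``probe_id``, ``probe_class``
  (``gene``/``neg_ctrl``), ``housekeeping`` (0/1), then one integer column
  per sample;
* metadata — TSV with ``sample_id``, ``sample_role``, ``group`` plus
  optional ``hscore_<gene>`` / ``ihc_<gene>`` columns;
* loci — 6-column BED (0-based, half-open);
* signatures — TSV with ``subtype``, ``gene``, ``direction`` in
  {``high``, ``low``}.

Lines starting with ``#`` are comments.  Readers validate and never drop
rows silently; writers emit a deterministic column order with ``\\n`` line
endings so byte-level reproducibility checks are meaningful.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    GeneLocusTable,
    ProbeCountMatrix,
    SampleTable,
    SignatureSet,
    ValidationError,
)

logger = logging.getLogger(__name__)

_COUNT_META_COLS = ["probe_id", "probe_class", "housekeeping"]


class ParseError(ValueError):
    """Raised when an input file cannot be parsed into a valid table."""


def _read_header(path: Path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return line.rstrip("\n").split("\t")
    raise ParseError(f"{path}: no header line found")


def read_counts(path) -> ProbeCountMatrix:
    """Read a probe-by-sample count TSV into a validated matrix."""
    path = Path(path)
    header = _read_header(path)
    if header[: len(_COUNT_META_COLS)] != _COUNT_META_COLS:
        raise ParseError(
            f"{path}: header must start with {_COUNT_META_COLS}, got {header[:3]}"
        )
    sample_cols = header[len(_COUNT_META_COLS) :]
    if len(set(sample_cols)) != len(sample_cols):
        dupes = pd.Series(sample_cols)
        raise ParseError(
            f"{path}: duplicated sample column(s): "
            f"{dupes[dupes.duplicated()].unique().tolist()}"
        )
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"probe_id": str})
    for col in sample_cols:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.number):
            bad = vals[pd.to_numeric(vals, errors="coerce").isna()]
            raise ParseError(
                f"{path}: non-numeric count in column {col!r}, "
                f"row {bad.index[0] + 2 if len(bad) else '?'}"
            )
        if not np.allclose(vals, np.round(vals)):
            raise ParseError(f"{path}: non-integer count in column {col!r}")
        if (vals < 0).any():
            row = int(vals[vals < 0].index[0])
            raise ParseError(f"{path}: negative count in column {col!r}, row {row + 2}")
    counts = df.set_index("probe_id")[sample_cols].astype(np.int64)
    try:
        pcm = ProbeCountMatrix(
            counts=counts,
            probe_class=df.set_index("probe_id")["probe_class"],
            housekeeping=df.set_index("probe_id")["housekeeping"].astype(bool),
        )
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    logger.info("read %d probes x %d samples from %s", len(df), len(sample_cols), path)
    return pcm


def write_counts(pcm: ProbeCountMatrix, path) -> None:
    path = Path(path)
    df = pcm.counts.copy()
    df.insert(0, "housekeeping", pcm.housekeeping.astype(int))
    df.insert(0, "probe_class", pcm.probe_class)
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_metadata(path) -> SampleTable:
    """Read the per-sample metadata TSV."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str, "group": str})
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing sample_id column")
    try:
        table = SampleTable(table=df.set_index("sample_id"))
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    logger.info("read %d samples from %s", len(df), path)
    return table


def write_metadata(samples: SampleTable, path) -> None:
    path = Path(path)
    df = samples.table.copy()
    fixed = ["sample_role", "group"]
    extra = sorted(c for c in df.columns if c not in fixed)
    df = df[fixed + extra]
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_bed(path) -> GeneLocusTable:
    """Read gene loci from a 6-column BED file (0-based, half-open)."""
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str, "gene_id": str, "strand": str},
    )
    if df["gene_id"].isna().any() or df["strand"].isna().any():
        raise ParseError(f"{path}: BED requires 6 columns (chrom start end name score strand)")
    try:
        table = GeneLocusTable(
            table=df.set_index("gene_id")[["chrom", "start", "end", "strand"]]
        )
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    logger.info("read %d loci from %s", len(df), path)
    return table


def write_bed(loci: GeneLocusTable, path) -> None:
    path = Path(path)
    df = loci.table.reset_index()
    df["score"] = 0
    df = df[["chrom", "start", "end", "gene_id", "score", "strand"]]
    df.to_csv(path, sep="\t", header=False, index=False, lineterminator="\n")


def read_signatures(path) -> list[SignatureSet]:
    """Read signed signature gene sets from a subtype/gene/direction TSV."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("subtype", "gene", "direction"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    bad = ~df["direction"].isin(["high", "low"])
    if bad.any():
        row = int(df.index[bad][0])
        raise ParseError(
            f"{path}: unknown direction {df.loc[row, 'direction']!r} at row {row + 2}"
        )
    sigs = []
    for name, grp in df.groupby("subtype", sort=True):
        try:
            sigs.append(
                SignatureSet(
                    name=str(name),
                    high=grp.loc[grp["direction"] == "high", "gene"].tolist(),
                    low=grp.loc[grp["direction"] == "low", "gene"].tolist(),
                )
            )
        except ValidationError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    logger.info("read %d signatures (%d rows) from %s", len(sigs), len(df), path)
    return sigs


def write_signatures(sigs: list[SignatureSet], path) -> None:
    path = Path(path)
    rows = []
    for sig in sorted(sigs, key=lambda s: s.name):
        rows.extend({"subtype": sig.name, "gene": g, "direction": "high"} for g in sig.high)
        rows.extend({"subtype": sig.name, "gene": g, "direction": "low"} for g in sig.low)
    pd.DataFrame(rows, columns=["subtype", "gene", "direction"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_gene_list(path) -> list[str]:
    """Read a one-gene-per-line list (e.g. a probe exclusion list)."""
    path = Path(path)
    genes = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line.split("\t")[0])
    return genes


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """Write any report table as TSV with deterministic formatting."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")
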