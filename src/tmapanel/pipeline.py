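"""End-to-end pipeline: QC -> normalization -> z-scores -> subtype calls ->
amplicon calls -> mRNA-protein concordance, with a provenance manifest.

Each stage writes its table as soon as it completes, so a failure in a late
stage leaves earlier outputs intact; the manifest records every file with a
SHA-256 checksum plus the full parameter set, and is deterministic for a
fixed configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as tio
from .amplicon import AmpliconConfig, call_amplicon, find_neighbors
from .concordance import ConcordanceConfig, discordance_flags, mrna_protein_by_group
from .qc import QcConfig, run_qc
from .signatures import assign_subtypes, reannotate, zscore

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline aborted at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    counts: str | Path
    metadata: str | Path
    loci: str | Path | None = None
    signatures: str | Path | None = None
    blacklist: str | Path | None = None
    output_dir: str | Path = "tmapanel_out"
    qc: QcConfig = field(default_factory=QcConfig)
    amplicon: AmpliconConfig = field(default_factory=AmpliconConfig)
    concordance: ConcordanceConfig = field(default_factory=ConcordanceConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, klass in (
            ("qc", QcConfig),
            ("amplicon", AmpliconConfig),
            ("concordance", ConcordanceConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Path):
        return str(obj)
    return obj


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage; returns the manifest path.

    Stage order: qc (sequencing filter + normalization + sample-quality
    filter) -> zscore -> classify (when signatures are supplied) ->
    amplicon (when loci are supplied) -> concordance (when H-scores are
    present).  A stage failure raises :class:`PipelineError` naming the
    stage, after writing a manifest of the outputs produced so far.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    stage = "setup"

    def emit(name: str, df: pd.DataFrame, index: bool = True) -> None:
        tio.write_table(df, out / name, index=index)
        outputs.append(name)

    def finish(error: str | None = None) -> Path:
        manifest = {
            "parameters": {
                "counts": str(cfg.counts),
                "metadata": str(cfg.metadata),
                "loci": str(cfg.loci) if cfg.loci else None,
                "signatures": str(cfg.signatures) if cfg.signatures else None,
                "blacklist": str(cfg.blacklist) if cfg.blacklist else None,
                "qc": _jsonable(cfg.qc),
                "amplicon": _jsonable(cfg.amplicon),
                "concordance": _jsonable(cfg.concordance),
                "seed": cfg.seed,
            },
            "outputs": [
                {"name": n, "sha256": _sha256(out / n)} for n in outputs
            ],
            "error": error,
        }
        path = out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
        return path

    try:
        stage = "qc"
        counts = tio.read_counts(cfg.counts)
        samples = tio.read_metadata(cfg.metadata)
        expr, qc_report = run_qc(counts, samples, cfg.qc)
        rep = qc_report.table.copy()
        rep.index.name = "sample_id"
        emit("qc_report.tsv", rep)
        ex = expr.values.copy()
        ex.index.name = "gene_id"
        emit("expression.tsv", ex)

        stage = "zscore"
        t = samples.table
        analysis_samples = [
            s
            for s in expr.values.columns
            if t.loc[s, "sample_role"] in ("tumor", "normal")
        ]
        zm = zscore(expr, analysis_samples)
        zdf = zm.z[analysis_samples].copy()
        zdf.index.name = "gene_id"
        emit("zscores.tsv", zdf)

        calls = None
        if cfg.signatures is not None:
            stage = "classify"
            sigs = tio.read_signatures(cfg.signatures)
            tumor = [s for s in analysis_samples if t.loc[s, "sample_role"] == "tumor"]
            calls = assign_subtypes(zm, sigs).loc[tumor]
            calls.index.name = "sample_id"
            emit("subtype_calls.tsv", calls)
            crosstab, _detail = reannotate(calls, samples)
            emit("reannotation_crosstab.tsv", crosstab)

        if cfg.loci is not None:
            stage = "amplicon"
            loci = tio.read_bed(cfg.loci)
            tumor = [s for s in analysis_samples if t.loc[s, "sample_role"] == "tumor"]
            zm_tumor = zscore(expr.subset_samples(tumor), tumor)
            neighborhood = find_neighbors(loci, cfg.amplicon)
            amp = call_amplicon(zm_tumor, neighborhood, cfg.amplicon)
            emit("amplicon_calls.tsv", amp)

        stage = "concordance"
        hs_genes = sorted(c.removeprefix("hscore_") for c in samples.hscore_columns)
        conc_rows = []
        for gene in hs_genes:
            if gene not in expr.values.index:
                continue
            rows, pooled = mrna_protein_by_group(expr, samples, gene, cfg.concordance)
            if len(rows) >= 3:
                rows = discordance_flags(rows, cfg.concordance)
            rows = rows.reset_index()
            rows.insert(0, "gene", gene)
            rows["pooled_r"] = pooled
            conc_rows.append(rows)
        if conc_rows:
            conc = pd.concat(conc_rows, ignore_index=True)
        else:
            conc = pd.DataFrame(
                columns=["gene", "group", "n", "median_mrna", "median_hscore",
                         "r_mrna_protein", "pooled_r"]
            )
        emit("mrna_protein_groups.tsv", conc, index=False)
    except Exception as exc:  # noqa: BLE001 - manifest must name the failed stage
        finish(error=f"{stage}: {exc}")
        raise PipelineError(stage, exc) from exc

    return finish()
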