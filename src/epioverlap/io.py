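"""Readers and writers for the package's plain-text interchange formats.

Formats: UCSC two-column chrom.sizes, a headered BED-like gene table,
GMT genesets, and headered summary-statistics TSV with columns
``site_id, chromosome, position, p_value[, effect]`` (common aliases such
as ``id/chr/pos/p/beta`` are accepted). Internally everything is 0-based
half-open; pass ``one_based=True`` for GTF-style gene coordinates.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    FormatError,
    GeneRecord,
    GenomeLayout,
    GenesetAnnotation,
    SiteRecord,
    StudyHits,
    ValidationError,
    validate_genes,
)

logger = logging.getLogger(__name__)

_COLUMN_ALIASES = {
    "site_id": ("site_id", "id", "name", "snp", "cpg", "probe_id"),
    "chromosome": ("chromosome", "chr", "chrom", "seqnames"),
    "position": ("position", "pos", "bp", "base_pair_location"),
    "p_value": ("p_value", "p", "pval", "pvalue", "p.value"),
    "effect": ("effect", "beta", "b", "estimate"),
}


def _resolve_columns(columns, required=("site_id", "chromosome", "position", "p_value")):
    lower = {c.lower(): c for c in columns}
    mapping = {}
    for canonical, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                mapping[canonical] = lower[alias]
                break
    for canonical in required:
        if canonical not in mapping:
            raise FormatError(f"required column {canonical!r} missing (have {list(columns)})")
    return mapping


def read_summary_stats(
    path,
    study_type: str,
    threshold: float | None = None,
    trait: str | None = None,
    sample_size: int | None = None,
) -> StudyHits:
    """Read a summary-statistics table and keep rows with p < threshold.

    Unparseable positions or p-values are reported with their 1-based
    line number (header = line 1) rather than silently dropped.
    """
    if threshold is None:
        threshold = StudyHits.default_threshold(study_type)
    if not (0.0 < threshold <= 1.0):
        raise ValidationError(f"threshold {threshold} outside (0, 1]")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = _resolve_columns(df.columns)

    def _numeric(col, kind):
        raw = df[cols[col]]
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna()
        if bad.any():
            lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()
            raise FormatError(
                f"{path.name}: unparseable {kind} value(s) at line(s) {lines[:10]}"
            )
        return vals.to_numpy()

    if len(df) == 0:
        return StudyHits(trait or path.stem, study_type, [], threshold, sample_size)
    positions = _numeric("position", "position").astype(np.int64)
    pvals = _numeric("p_value", "p-value").astype(float)
    effects = None
    if "effect" in cols:
        raw = pd.to_numeric(df[cols["effect"]], errors="coerce")
        effects = raw.to_numpy(dtype=float)

    keep = pvals < threshold
    logger.info(
        "%s: %d rows read, %d pass p < %.3g, %d discarded",
        path.name, len(df), int(keep.sum()), threshold, int((~keep).sum()),
    )
    sites = [
        SiteRecord(
            site_id=str(df[cols["site_id"]].iloc[i]),
            chromosome=str(df[cols["chromosome"]].iloc[i]),
            position=int(positions[i]),
            p_value=float(pvals[i]),
            effect=(None if effects is None or np.isnan(effects[i]) else float(effects[i])),
        )
        for i in np.flatnonzero(keep)
    ]
    return StudyHits(trait or path.stem, study_type, sites, threshold, sample_size)


def read_gmt(path, universe: set[str] | None = None) -> GenesetAnnotation:
    """Parse a GMT file: one geneset per line, tab-separated
    ``id <TAB> description <TAB> member...``."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            gs_id, desc, *members = fields
            if gs_id in sets:
                raise FormatError(f"GMT line {lineno}: duplicate geneset id {gs_id!r}")
            sets[gs_id] = set(m for m in members if m)
            descriptions[gs_id] = desc
    return GenesetAnnotation(sets, universe=universe, descriptions=descriptions)


def read_genome(
    path_sizes, path_genes, one_based: bool = False
) -> tuple[GenomeLayout, list[GeneRecord]]:
    """Read a chrom.sizes table and a gene table; validate jointly.

    The gene table is tab-separated with a header naming at least
    ``gene_id, chromosome, start, end`` (``biotype`` optional).
    """
    sizes = pd.read_csv(
        path_sizes, sep="\t", header=None, names=["chromosome", "length"],
        dtype={"chromosome": str, "length": np.int64},
    )
    layout = GenomeLayout(
        tuple((str(r.chromosome), int(r.length)) for r in sizes.itertuples())
    )
    gdf = pd.read_csv(path_genes, sep="\t", dtype={"chromosome": str})
    needed = {"gene_id", "chromosome", "start", "end"}
    if not needed <= set(gdf.columns):
        raise FormatError(f"gene table missing columns {sorted(needed - set(gdf.columns))}")
    shift = 1 if one_based else 0
    genes = [
        GeneRecord(
            gene_id=str(r.gene_id),
            chromosome=str(r.chromosome),
            start=int(r.start) - shift,
            end=int(r.end),
            biotype=str(getattr(r, "biotype", "protein_coding")),
        )
        for r in gdf.itertuples()
    ]
    validate_genes(genes, layout)
    return layout, genes


def write_results_table(rows, path) -> None:
    """Write homogeneous result records as a headered TSV.

    Accepts a DataFrame, a list of dataclasses, or a list of dicts.
    Floats are written with full round-trip precision so that reading
    the file back reproduces the values exactly.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        records = [r.__dict__ if hasattr(r, "__dict__") else dict(r) for r in rows]
        df = pd.DataFrame.from_records(records)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_run_metadata(path, config, extra: dict | None = None) -> None:
    meta = {"config": config.__dict__, **(extra or {})}
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
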