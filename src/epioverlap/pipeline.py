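"""Per-trait orchestration: map -> overlap -> nulls -> result tables.

``run_trait`` executes the full observed analysis for one GWAS/EWAS
pair (region tally, gene overlap, geneset overlap, enrichment
correlation) plus both resampling nulls, and writes every table it
reports. ``run_all`` iterates a manifest of trait pairs, isolates
per-trait failures, and applies a cross-trait Benjamini-Hochberg
correction to the null-comparison p-values.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io, mapping, nulls, stats
from .stats import bh_fdr
from .types import RunConfig

logger = logging.getLogger(__name__)


@dataclass
class PipelineReport:
    trait: str
    region_tally: mapping.RegionTally
    n_ewas_genes: int
    n_gwas_genes: int
    gene_overlap: stats.OverlapResult
    geneset_overlap: stats.OverlapResult
    enrichment_correlation: float
    expected: dict[str, dict[str, float]] = field(default_factory=dict)
    # expected[null_scheme][statistic] -> {"expected": ..., "p_diff": ...}
    provenance: dict = field(default_factory=dict)

    def summary_row(self) -> dict:
        rnd = self.expected.get("random_position", {})
        row = {
            "trait": self.trait,
            "n_ewas_genes": self.n_ewas_genes,
            "n_gwas_genes": self.n_gwas_genes,
            "gene_overlap": self.gene_overlap.table.a,
            "obs_or": self.gene_overlap.odds_ratio,
            "geneset_overlap": self.geneset_overlap.table.a,
            "obs_cor": self.enrichment_correlation,
        }
        for statname, short in (
            (nulls.GENE_OVERLAP_OR, "or"),
            (nulls.ENRICHMENT_CORRELATION, "cor"),
        ):
            if statname in rnd:
                row[f"exp_{short}"] = rnd[statname]["expected"]
                row[f"p_diff_{short}"] = rnd[statname]["p_diff"]
        return row


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_trait(
    gwas_path,
    ewas_path,
    chrom_sizes_path,
    genes_path,
    gmt_path,
    config: RunConfig | None = None,
    out_dir=None,
    trait: str | None = None,
    null_schemes: tuple[str, ...] = ("random_position", "shifted_position"),
    requests: tuple[str, ...] = (
        nulls.GENE_OVERLAP_OR,
        nulls.ENRICHMENT_CORRELATION,
    ),
) -> PipelineReport:
    """Full observed + expected analysis for one GWAS/EWAS trait pair."""
    config = config or RunConfig()
    layout, genes = io.read_genome(chrom_sizes_path, genes_path)
    if config.universe_mode == "protein_coding":
        genes = [g for g in genes if g.biotype == "protein_coding"]
    universe = {g.gene_id for g in genes}
    annotation = io.read_gmt(gmt_path, universe=universe)
    gwas = io.read_summary_stats(gwas_path, "gwas", config.gwas_p, trait=trait)
    ewas = io.read_summary_stats(ewas_path, "ewas", config.ewas_p, trait=trait)
    trait = trait or ewas.trait

    # region co-occurrence, using the full probe panel (all EWAS rows)
    ewas_all = io.read_summary_stats(ewas_path, "ewas", 1.0, trait=trait)
    region_p = mapping.resolve_region_threshold(
        max((s.p_value for s in ewas_all.sites), default=1.0), config.region_p
    )
    logger.info("%s: region threshold resolved to %.3g", trait, region_p)
    regions = mapping.filter_regions(
        mapping.bin_genome(layout, config.region_width), ewas_all.sites
    )
    gwas_lenient = io.read_summary_stats(gwas_path, "gwas", 1.0, trait=trait)
    tally = mapping.tally_regions(regions, gwas_lenient, ewas_all, region_p)

    gmap = mapping.map_sites_to_genes(gwas.sites, genes)
    emap = mapping.map_sites_to_genes(ewas.sites, genes)
    gov = stats.gene_overlap(emap.genes, gmap.genes, universe)
    pg = stats.enrichment_profile(gmap.genes, annotation, study=f"{trait}:gwas")
    pe = stats.enrichment_profile(emap.genes, annotation, study=f"{trait}:ewas")
    pov = stats.geneset_overlap(pe, pg)
    rho = stats.enrichment_correlation(pe, pg)

    observed = {
        nulls.GENE_OVERLAP_OR: gov.odds_ratio,
        nulls.GENESET_OVERLAP_OR: pov.odds_ratio,
        nulls.ENRICHMENT_CORRELATION: rho,
    }
    expected: dict[str, dict[str, dict[str, float]]] = {}
    if "random_position" in null_schemes:
        dists = nulls.random_position_null(
            len(ewas.sites), layout, genes, gmap.genes, universe,
            reps=config.resample_reps, seed=config.rng_seed,
            annotation=annotation, gwas_profile=pg, requests=requests,
        )
        expected["random_position"] = {
            k: dict(zip(("expected", "p_diff"),
                        nulls.expected_overlap_summary(observed[k], d)))
            for k, d in dists.items()
        }
    if "shifted_position" in null_schemes:
        dists = nulls.shifted_position_null_distribution(
            ewas.sites, layout, genes, gmap.genes, universe,
            reps=config.resample_reps,
            annotation=annotation, gwas_profile=pg, requests=requests,
        )
        expected["shifted_position"] = {
            k: dict(zip(("expected", "p_diff"),
                        nulls.expected_overlap_summary(observed[k], d)))
            for k, d in dists.items()
        }

    report = PipelineReport(
        trait=trait,
        region_tally=tally,
        n_ewas_genes=len(emap.genes),
        n_gwas_genes=len(gmap.genes),
        gene_overlap=gov,
        geneset_overlap=pov,
        enrichment_correlation=rho,
        expected=expected,
        provenance={
            "seed": config.rng_seed,
            "region_p": region_p,
            "resample_reps": config.resample_reps,
            "inputs": {
                "gwas": _digest(gwas_path),
                "ewas": _digest(ewas_path),
                "genes": _digest(genes_path),
                "gmt": _digest(gmt_path),
            },
        },
    )
    if out_dir is not None:
        _write_trait_outputs(report, gmap, emap, out_dir, config)
    return report


def _write_trait_outputs(report, gmap, emap, out_dir, config):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_results_table(
        pd.DataFrame([report.summary_row()]), out / f"{report.trait}_overlap.tsv"
    )
    tally_df = pd.DataFrame(
        [{"category": k, "count": v} for k, v in report.region_tally.counts.items()]
    )
    io.write_results_table(tally_df, out / f"{report.trait}_region_tally.tsv")
    for name, m in (("gwas", gmap), ("ewas", emap)):
        trace = pd.DataFrame(
            [
                {"site_id": sid, "gene_ids": ",".join(gs)}
                for sid, gs in sorted(m.trace.items())
            ]
        )
        io.write_results_table(trace, out / f"{report.trait}_{name}_gene_map.tsv")
    io.write_run_metadata(
        out / f"{report.trait}_run.json", config, extra=report.provenance
    )


def run_all(manifest: list[dict], config: RunConfig | None = None, out_dir=None):
    """Run every trait pair in a manifest; failures are isolated.

    Each manifest row: trait, gwas, ewas, chrom_sizes, genes, gmt.
    Returns (combined summary DataFrame with cross-trait FDR, failures).
    """
    config = config or RunConfig()
    reports, failures = [], []
    for row in manifest:
        try:
            reports.append(
                run_trait(
                    row["gwas"], row["ewas"], row["chrom_sizes"],
                    row["genes"], row["gmt"], config=config,
                    out_dir=out_dir, trait=row.get("trait"),
                )
            )
        except Exception as exc:  # noqa: BLE001 - isolation contract
            logger.error("trait %r failed: %s", row.get("trait"), exc)
            failures.append({"trait": row.get("trait"), "error": str(exc)})
    combined = pd.DataFrame([r.summary_row() for r in reports])
    if not combined.empty:
        for col in ("p_diff_or", "p_diff_cor"):
            if col in combined:
                combined[f"{col}_fdr"] = bh_fdr(combined[col].to_numpy())
    if out_dir is not None and not combined.empty:
        io.write_results_table(combined, Path(out_dir) / "combined_overlap.tsv")
    return combined, failures
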