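"""Synthetic genomes, genesets and GWAS/EWAS summary statistics with a
known causal/associated gene architecture.

The generator emulates the study design under test: a pool of *causal*
genes (genes influencing the trait — what GWAS hits tag) and a pool of
*associated* genes (genes correlating with the trait through causation,
confounding or reverse causation — what EWAS hits tag), with a
configurable overlap between the pools. Each study has a detection
power: the probability that a signal gene's best site reaches the
study's significance threshold. Background sites carry Uniform(0,1]
p-values. Every emitted table comes with its ground truth, so
downstream mapping and overlap stages can be validated exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    GeneRecord,
    GenomeLayout,
    GenesetAnnotation,
    StudyHits,
    ValidationError,
    child_rng,
)

MIN_SIGNAL_P = 1e-30  # lower bound of the log-uniform sub-threshold draw


@dataclass(frozen=True)
class TraitArchitecture:
    """Ground-truth gene pools for one trait."""

    causal_genes: frozenset
    associated_genes: frozenset
    overlap_proportion: float

    def __post_init__(self):
        if self.associated_genes:
            got = len(self.causal_genes & self.associated_genes)
            want = round(self.overlap_proportion * len(self.associated_genes))
            if got != want:
                raise ValidationError(
                    f"overlap {got} does not match proportion "
                    f"{self.overlap_proportion} of {len(self.associated_genes)}"
                )


@dataclass(frozen=True)
class StudyDesign:
    study_type: str  # {"gwas", "ewas"}
    power: float = 1.0  # P(signal gene's best site passes threshold)
    n_sites_per_gene: int = 3
    panel_density: float = 10.0  # background sites per megabase

    def __post_init__(self):
        if not (0.0 <= self.power <= 1.0):
            raise ValidationError("power must lie in [0, 1]")
        if self.n_sites_per_gene < 1:
            raise ValidationError("n_sites_per_gene must be positive")
        if self.study_type not in ("gwas", "ewas"):
            raise ValidationError(f"unknown study type {self.study_type!r}")


def generate_genome(
    n_chromosomes: int,
    chrom_length: int,
    n_genes: int,
    gene_length_range: tuple[int, int] = (1_000, 50_000),
    seed: int = 0,
    protein_coding_fraction: float = 0.8,
) -> tuple[GenomeLayout, list[GeneRecord]]:
    """Equal-length chromosomes with non-overlapping, uniformly spread genes.

    Genes are dealt round-robin across chromosomes; per chromosome the
    free space between genes is split by a symmetric multinomial draw,
    giving uniform placement without overlap. Raises when the requested
    gene footprint cannot fit.
    """
    lo, hi = gene_length_range
    if lo <= 0 or hi < lo:
        raise ValidationError("invalid gene length range")
    rng = child_rng(seed, "genome")
    layout = GenomeLayout(
        tuple((f"chr{i + 1}", int(chrom_length)) for i in range(n_chromosomes))
    )
    per_chrom = [n_genes // n_chromosomes + (1 if i < n_genes % n_chromosomes else 0)
                 for i in range(n_chromosomes)]
    genes: list[GeneRecord] = []
    gid = 0
    for ci, (chrom, length) in enumerate(layout.chromosomes):
        k = per_chrom[ci]
        if k == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=k)
        free = length - int(lengths.sum())
        if free < 0:
            raise ValidationError(
                f"gene footprint {int(lengths.sum())} exceeds {chrom} length {length}"
            )
        gaps = rng.multinomial(free, np.full(k + 1, 1.0 / (k + 1)))
        start = 0
        for j in range(k):
            start += int(gaps[j])
            end = start + int(lengths[j])
            biotype = (
                "protein_coding"
                if rng.random() < protein_coding_fraction
                else "other"
            )
            genes.append(GeneRecord(f"gene_{gid:05d}", chrom, start, end, biotype))
            gid += 1
            start = end
    return layout, genes


def generate_genesets(
    genes: list[GeneRecord],
    n_sets: int,
    size_range: tuple[int, int] = (10, 200),
    broad_fraction: float = 0.3,
    seed: int = 0,
) -> GenesetAnnotation:
    """Random genesets mimicking ontology annotations: a configurable
    fraction of sets are 'broad' (> 100 members), the rest 'narrow'."""
    if n_sets < 1:
        raise ValidationError("n_sets must be >= 1")
    lo, hi = size_range
    ids = [g.gene_id for g in genes]
    if hi > len(ids):
        raise ValidationError(f"requested set size {hi} exceeds universe {len(ids)}")
    n_broad = round(broad_fraction * n_sets)
    if n_broad > 0 and hi <= 100:
        raise ValidationError("broad sets requested but max size <= 100")
    rng = child_rng(seed, "genesets")
    sets = {}
    for i in range(n_sets):
        if i < n_broad:
            size = int(rng.integers(max(lo, 101), hi + 1))
        else:
            size = int(rng.integers(lo, min(hi, 100) + 1))
        members = rng.choice(ids, size=size, replace=False)
        sets[f"GS{i:04d}"] = set(members.tolist())
    return GenesetAnnotation(sets, universe=set(ids))


def generate_architecture(
    genes: list[GeneRecord],
    n_causal: int,
    n_associated: int,
    overlap_proportion: float,
    seed: int = 0,
) -> TraitArchitecture:
    """Sample causal and associated gene pools with a fixed overlap.

    The overlap is exact: round(overlap_proportion * n_associated)
    associated genes are also causal.
    """
    if not (0.0 <= overlap_proportion <= 1.0):
        raise ValidationError("overlap_proportion must lie in [0, 1]")
    ids = [g.gene_id for g in genes]
    n_overlap = round(overlap_proportion * n_associated)
    n_needed = n_causal + n_associated - n_overlap
    if n_needed > len(ids) or n_overlap > min(n_causal, n_associated):
        raise ValidationError(
            f"infeasible architecture: need {n_needed} distinct genes "
            f"(universe {len(ids)}), overlap {n_overlap}"
        )
    rng = child_rng(seed, "architecture")
    drawn = rng.choice(ids, size=n_needed, replace=False)
    causal = set(drawn[:n_causal].tolist())
    associated = set(drawn[:n_overlap].tolist()) | set(
        drawn[n_causal:].tolist()
    )
    return TraitArchitecture(
        frozenset(causal), frozenset(associated), overlap_proportion
    )


@dataclass
class StudyTruth:
    """Ground truth emitted alongside a simulated summary-stats table."""

    signal_genes: set[str]  # the pool the study samples from
    detected_genes: set[str]  # genes given a sub-threshold best site
    site_to_gene: dict[str, str]  # signal sites only
    threshold: float


def generate_study(
    architecture: TraitArchitecture,
    design: StudyDesign,
    genome: GenomeLayout,
    genes: list[GeneRecord],
    seed: int = 0,
    trait: str = "synthetic_trait",
) -> tuple[pd.DataFrame, StudyTruth]:
    """Simulate a full summary-statistics table (all sites, not only hits).

    GWAS signal comes from the causal pool, EWAS signal from the
    associated pool. Each signal gene gets ``n_sites_per_gene`` sites
    inside its body; with probability ``power`` one of them receives a
    sub-threshold p-value drawn log-uniformly on [1e-30, threshold).
    Background sites are placed uniformly at ``panel_density`` per Mb
    with Uniform(0,1] p-values.
    """
    rng = child_rng(seed, "study", design.study_type, trait)
    threshold = StudyHits.default_threshold(design.study_type)
    pool = (
        architecture.causal_genes
        if design.study_type == "gwas"
        else architecture.associated_genes
    )
    by_id = {g.gene_id: g for g in genes}
    missing = pool - set(by_id)
    if missing:
        raise ValidationError(f"architecture gene(s) not in gene models: {sorted(missing)[:5]}")

    rows = []
    truth = StudyTruth(set(pool), set(), {}, threshold)
    prefix = "rs" if design.study_type == "gwas" else "cg"
    counter = 0
    for gene_id in sorted(pool):
        g = by_id[gene_id]
        positions = rng.integers(g.start, g.end, size=design.n_sites_per_gene)
        pvals = rng.uniform(0.0, 1.0, size=design.n_sites_per_gene)
        pvals = np.nextafter(pvals, 1.0)  # keep within (0, 1]
        effects = rng.normal(0.0, 0.05, size=design.n_sites_per_gene)
        if rng.random() < design.power:
            truth.detected_genes.add(gene_id)
            best = rng.integers(design.n_sites_per_gene)
            log_p = rng.uniform(np.log(MIN_SIGNAL_P), np.log(threshold))
            pvals[best] = np.exp(log_p)
            effects[best] = rng.choice([-1.0, 1.0]) * rng.normal(0.25, 0.05)
        for pos, p, eff in zip(positions, pvals, effects):
            sid = f"{prefix}{counter:07d}"
            counter += 1
            rows.append((sid, g.chromosome, int(pos), float(p), float(eff)))
            truth.site_to_gene[sid] = gene_id

    n_bg = round(design.panel_density * genome.total_length / 1e6)
    if n_bg > 0:
        offsets = np.concatenate([[0], np.cumsum(genome.lengths)])
        flat = rng.integers(0, genome.total_length, size=n_bg)
        chrom_idx = np.searchsorted(offsets, flat, side="right") - 1
        local = flat - offsets[chrom_idx]
        bg_p = np.nextafter(rng.uniform(0.0, 1.0, size=n_bg), 1.0)
        bg_eff = rng.normal(0.0, 0.05, size=n_bg)
        names = genome.names
        for ci, pos, p, eff in zip(chrom_idx, local, bg_p, bg_eff):
            rows.append(
                (f"{prefix}{counter:07d}", names[ci], int(pos), float(p), float(eff))
            )
            counter += 1

    df = pd.DataFrame(
        rows, columns=["site_id", "chromosome", "position", "p_value", "effect"]
    )
    return df, truth


def write_bundle(
    out_dir,
    layout: GenomeLayout,
    genes: list[GeneRecord],
    annotation: GenesetAnnotation,
    gwas_table: pd.DataFrame,
    ewas_table: pd.DataFrame,
    truth: dict,
) -> dict[str, Path]:
    """Write a complete analysis input bundle as plain-text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "chrom_sizes": out / "chrom.sizes",
        "genes": out / "genes.tsv",
        "gmt": out / "genesets.gmt",
        "gwas": out / "gwas.tsv",
        "ewas": out / "ewas.tsv",
        "truth": out / "truth.json",
    }
    with open(paths["chrom_sizes"], "w") as fh:
        for name, length in layout.chromosomes:
            fh.write(f"{name}\t{length}\n")
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chromosome": [g.chromosome for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "biotype": [g.biotype for g in genes],
        }
    ).to_csv(paths["genes"], sep="\t", index=False)
    with open(paths["gmt"], "w") as fh:
        for gs_id in annotation.geneset_ids:
            members = "\t".join(sorted(annotation.sets[gs_id]))
            desc = annotation.descriptions.get(gs_id, "synthetic geneset")
            fh.write(f"{gs_id}\t{desc}\t{members}\n")
    gwas_table.to_csv(paths["gwas"], sep="\t", index=False, float_format="%.17g")
    ewas_table.to_csv(paths["ewas"], sep="\t", index=False, float_format="%.17g")
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, default=lambda o: sorted(o) if isinstance(o, (set, frozenset)) else str(o))
    return paths
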