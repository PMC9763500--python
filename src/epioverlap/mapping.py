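"""Genome binning, region co-occurrence tallies and site-to-gene mapping.

The region analysis tiles each chromosome into fixed-width blocks
(500 kb by default), drops blocks with no methylation probe, and counts
how many retained blocks contain significant GWAS sites, EWAS sites,
both or neither. The gene analysis maps each significant site to its
nearest gene: all genes whose body contains the site, otherwise the
gene(s) at minimal distance to a gene edge on the same chromosome —
ties map to all tied genes and a site never maps across chromosomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .stats import AucResult, rank_auc
from .types import (
    GeneRecord,
    GenomeLayout,
    SiteRecord,
    StudyHits,
    ValidationError,
    genes_by_chromosome,
)

logger = logging.getLogger(__name__)

REGION_CATEGORIES = ("neither", "gwas_only", "ewas_only", "both")


@dataclass(frozen=True)
class Region:
    chromosome: str
    start: int
    end: int
    contains_probe: bool = False


@dataclass
class RegionTally:
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def bin_genome(layout: GenomeLayout, width: int) -> list[Region]:
    """Tile every chromosome into ceil(length/width) half-open blocks;
    the last block on a chromosome may be short."""
    if width <= 0:
        raise ValidationError("region width must be positive")
    regions = []
    for name, length in layout.chromosomes:
        starts = np.arange(0, length, width, dtype=np.int64)
        for s in starts:
            regions.append(Region(name, int(s), int(min(s + width, length))))
    return regions


def _positions_by_chrom(sites) -> dict[str, np.ndarray]:
    out: dict[str, list[int]] = {}
    for s in sites:
        out.setdefault(s.chromosome, []).append(s.position)
    return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}


def filter_regions(regions: list[Region], probes: list[SiteRecord]) -> list[Region]:
    """Keep only regions containing >= 1 probe; order preserved."""
    pos = _positions_by_chrom(probes)
    kept = []
    for r in regions:
        p = pos.get(r.chromosome)
        if p is not None and bool(np.any((p >= r.start) & (p < r.end))):
            kept.append(Region(r.chromosome, r.start, r.end, contains_probe=True))
    return kept


def resolve_region_threshold(ewas_max_p: float, lenient_p: float = 1e-5) -> float:
    """Region-tally threshold: the lenient cut-off, or the maximum
    p-value reported in the EWAS when that is lower."""
    return min(lenient_p, ewas_max_p)


def tally_regions(
    regions: list[Region], gwas: StudyHits, ewas: StudyHits, region_p: float
) -> RegionTally:
    """Assign each retained region one of four co-occurrence categories."""
    chroms = {r.chromosome for r in regions}
    for study in (gwas, ewas):
        for s in study.sites:
            if s.chromosome not in chroms:
                raise ValidationError(
                    f"site {s.site_id!r} on chromosome {s.chromosome!r} "
                    "absent from the region set"
                )
    gpos = _positions_by_chrom([s for s in gwas.sites if s.p_value < region_p])
    epos = _positions_by_chrom([s for s in ewas.sites if s.p_value < region_p])
    counts = {k: 0 for k in REGION_CATEGORIES}
    for r in regions:
        g = gpos.get(r.chromosome)
        e = epos.get(r.chromosome)
        has_g = g is not None and bool(np.any((g >= r.start) & (g < r.end)))
        has_e = e is not None and bool(np.any((e >= r.start) & (e < r.end)))
        key = ("both" if has_g and has_e
               else "gwas_only" if has_g
               else "ewas_only" if has_e
               else "neither")
        counts[key] += 1
    return RegionTally(counts)


def region_effect_auc(
    regions: list[Region], gwas_sites: list[SiteRecord], ewas: StudyHits
) -> AucResult:
    """Can the largest |GWAS effect| in a region predict an EWAS hit there?

    Score = max |effect| over GWAS sites in the region; label = whether
    the region contains >= 1 significant EWAS site. Regions with no
    effect-bearing GWAS site are dropped (and counted in the log).
    """
    eff_sites = [s for s in gwas_sites if s.effect is not None]
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c, _ in _positions_by_chrom(eff_sites).items():
        sel = [s for s in eff_sites if s.chromosome == c]
        by_chrom[c] = (
            np.asarray([s.position for s in sel], dtype=np.int64),
            np.abs(np.asarray([s.effect for s in sel], dtype=float)),
        )
    epos = _positions_by_chrom(ewas.sites)
    scores, labels, dropped = [], [], 0
    for r in regions:
        pe = by_chrom.get(r.chromosome)
        if pe is None:
            dropped += 1
            continue
        pos, eff = pe
        inside = (pos >= r.start) & (pos < r.end)
        if not inside.any():
            dropped += 1
            continue
        scores.append(float(eff[inside].max()))
        e = epos.get(r.chromosome)
        labels.append(
            int(e is not None and bool(np.any((e >= r.start) & (e < r.end))))
        )
    if dropped:
        logger.info("region_effect_auc: %d region(s) without GWAS effects dropped", dropped)
    if len(set(labels)) < 2:
        raise ValidationError("AUC undefined: all region labels identical")
    return rank_auc(scores, labels)


@dataclass
class GeneMapping:
    """Many-to-many site -> gene assignment with per-site trace."""

    genes: set[str]
    trace: dict[str, tuple[str, ...]] = field(default_factory=dict)
    unmapped: list[str] = field(default_factory=list)


def map_positions_to_genes(
    chromosomes: np.ndarray,
    positions: np.ndarray,
    gene_index: dict[str, dict[str, np.ndarray]],
) -> list[tuple[str, ...]]:
    """Vectorised nearest-gene lookup for parallel position arrays.

    Returns, per site, the tuple of assigned gene ids (empty when the
    chromosome carries no genes). Distance to a gene is 0 inside the
    body, else base pairs to the nearer edge (half-open coordinates).
    """
    out: list[tuple[str, ...]] = []
    for chrom, pos in zip(chromosomes, positions):
        g = gene_index.get(chrom)
        if g is None or len(g["start"]) == 0:
            out.append(())
            continue
        start, end = g["start"], g["end"]
        dist = np.where(
            pos < start, start - pos, np.where(pos >= end, pos - end + 1, 0)
        )
        dmin = dist.min()
        out.append(tuple(g["gene_id"][dist == dmin]))
    return out


def map_sites_to_genes(
    sites: list[SiteRecord], genes: list[GeneRecord]
) -> GeneMapping:
    """Map sites to their containing gene(s), else the nearest gene(s)."""
    index = genes_by_chromosome(genes)
    chroms = np.asarray([s.chromosome for s in sites], dtype=object)
    pos = np.asarray([s.position for s in sites], dtype=np.int64)
    assigned = map_positions_to_genes(chroms, pos, index)
    mapping = GeneMapping(genes=set())
    for site, hit in zip(sites, assigned):
        if not hit:
            mapping.unmapped.append(site.site_id)
            continue
        mapping.trace[site.site_id] = hit
        mapping.genes.update(hit)
    if mapping.unmapped:
        logger.warning(
            "%d site(s) on chromosomes without genes left unmapped",
            len(mapping.unmapped),
        )
    return mapping
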