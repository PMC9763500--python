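"""Expected-overlap null distributions.

Two resampling schemes generate the "expected" counterpart of each
observed overlap statistic:

* **random positions** — per repetition, draw as many uniform genomic
  positions as the study had significant sites, map them to genes, and
  recompute the requested statistics against the fixed GWAS results;
* **shifted positions** — advance every observed site by a fixed
  offset, ``max gene size x iteration``, along the concatenated
  genome (wrapping from the last chromosome back to the first). This
  preserves the hit list's internal spacing, hence approximately its
  local correlation structure.

A z-test of the observed statistic against the null's mean and sd
yields the reported ``p_diff``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import stats
from .mapping import map_positions_to_genes
from .stats import EnrichmentProfile, NullDistribution
from .types import (
    GeneRecord,
    GenomeLayout,
    GenesetAnnotation,
    SiteRecord,
    ValidationError,
    child_rng,
    genes_by_chromosome,
)

logger = logging.getLogger(__name__)

GENE_OVERLAP_OR = "gene_overlap_or"
GENESET_OVERLAP_OR = "geneset_overlap_or"
ENRICHMENT_CORRELATION = "enrichment_correlation"
SUPPORTED_STATISTICS = (GENE_OVERLAP_OR, GENESET_OVERLAP_OR, ENRICHMENT_CORRELATION)


@dataclass(frozen=True)
class ShiftConfig:
    max_gene_size: int
    iteration: int
    wrap_order: tuple[str, ...]

    def __post_init__(self):
        if self.max_gene_size <= 0:
            raise ValidationError("max_gene_size must be positive")
        if self.iteration < 1:
            raise ValidationError("iteration must be >= 1")


def max_gene_size(genes: list[GeneRecord]) -> int:
    """The global maximum gene length — the fixed per-iteration shift."""
    return max(g.end - g.start for g in genes)


def sample_positions(
    n: int, layout: GenomeLayout, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """n positions uniform over the concatenated genome (length-weighted
    per chromosome); returns parallel (chromosome, position) arrays."""
    offsets = np.concatenate([[0], np.cumsum(layout.lengths)])
    flat = rng.integers(0, layout.total_length, size=n)
    idx = np.searchsorted(offsets, flat, side="right") - 1
    names = np.asarray(layout.names, dtype=object)
    return names[idx], flat - offsets[idx]


def _statistics_for_positions(
    chroms: np.ndarray,
    positions: np.ndarray,
    gene_index,
    gwas_genes: set[str],
    universe: set[str],
    annotation: GenesetAnnotation | None,
    gwas_profile: EnrichmentProfile | None,
    requests: tuple[str, ...],
) -> dict[str, float]:
    mapped = map_positions_to_genes(chroms, positions, gene_index)
    genes = set()
    for hit in mapped:
        genes.update(hit)
    out = {}
    if GENE_OVERLAP_OR in requests:
        e, g = genes, gwas_genes
        a = len(e & g)
        b = len(e - g)
        c = len(g - e)
        d = len(universe) - len(e | g)
        out[GENE_OVERLAP_OR] = stats.cross_product_or(a, b, c, d)
    if GENESET_OVERLAP_OR in requests or ENRICHMENT_CORRELATION in requests:
        profile = stats.enrichment_profile(genes, annotation, study="null")
        if GENESET_OVERLAP_OR in requests:
            out[GENESET_OVERLAP_OR] = stats.geneset_overlap(
                profile, gwas_profile
            ).odds_ratio
        if ENRICHMENT_CORRELATION in requests:
            out[ENRICHMENT_CORRELATION] = stats.enrichment_correlation(
                profile, gwas_profile
            )
    return out


def random_position_null(
    n_sites: int,
    layout: GenomeLayout,
    genes: list[GeneRecord],
    gwas_genes: set[str],
    universe: set[str],
    reps: int = 1000,
    seed: int = 0,
    annotation: GenesetAnnotation | None = None,
    gwas_profile: EnrichmentProfile | None = None,
    requests: tuple[str, ...] = (GENE_OVERLAP_OR,),
) -> dict[str, NullDistribution]:
    """Random-position expected-overlap null.

    Per repetition: ``n_sites`` uniform positions, mapped to genes
    exactly as observed sites are, then each requested statistic is
    recomputed against the fixed GWAS gene set / enrichment profile.
    """
    if n_sites < 1:
        raise ValidationError("n_sites must be >= 1 (no significant sites)")
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    for r in requests:
        if r not in SUPPORTED_STATISTICS:
            raise ValidationError(f"unknown statistic {r!r}")
    needs_profile = set(requests) & {GENESET_OVERLAP_OR, ENRICHMENT_CORRELATION}
    if needs_profile and (annotation is None or gwas_profile is None):
        raise ValidationError("geneset statistics need annotation and gwas_profile")
    gene_index = genes_by_chromosome(genes)
    draws: dict[str, list[float]] = {r: [] for r in requests}
    for i in range(reps):
        rng = child_rng(seed, "random_position_null", i)
        chroms, pos = sample_positions(n_sites, layout, rng)
        vals = _statistics_for_positions(
            chroms, pos, gene_index, gwas_genes, universe,
            annotation, gwas_profile, tuple(requests),
        )
        for k, v in vals.items():
            draws[k].append(v)
    return {k: NullDistribution(k, np.asarray(v)) for k, v in draws.items()}


def shifted_position_null(
    dmps: list[SiteRecord], config: ShiftConfig, layout: GenomeLayout
) -> list[SiteRecord]:
    """Advance every site by ``max_gene_size x iteration`` along the
    concatenated genome, wrapping last chromosome -> first."""
    if not dmps:
        raise ValidationError("no sites to shift")
    if list(config.wrap_order) != layout.names:
        raise ValidationError("wrap_order must match the layout's chromosome order")
    total = layout.total_length
    shift = config.max_gene_size * config.iteration
    if shift >= total:
        logger.info("shift %d >= genome length %d; reduced modulo", shift, total)
        shift %= total
    offsets = layout.offsets()
    bounds = np.concatenate([[0], np.cumsum(layout.lengths)])
    names = layout.names
    out = []
    for s in dmps:
        flat = offsets[s.chromosome] + s.position
        new_flat = (flat + shift) % total
        ci = int(np.searchsorted(bounds, new_flat, side="right") - 1)
        out.append(
            SiteRecord(
                site_id=s.site_id,
                chromosome=names[ci],
                position=int(new_flat - bounds[ci]),
                p_value=s.p_value,
                effect=s.effect,
            )
        )
    return out


def shifted_position_null_distribution(
    dmps: list[SiteRecord],
    layout: GenomeLayout,
    genes: list[GeneRecord],
    gwas_genes: set[str],
    universe: set[str],
    reps: int = 1000,
    annotation: GenesetAnnotation | None = None,
    gwas_profile: EnrichmentProfile | None = None,
    requests: tuple[str, ...] = (GENE_OVERLAP_OR,),
) -> dict[str, NullDistribution]:
    """Null built from iterations I = 1..reps of the shifted scheme."""
    gene_index = genes_by_chromosome(genes)
    shift_unit = max_gene_size(genes)
    draws: dict[str, list[float]] = {r: [] for r in requests}
    for i in range(1, reps + 1):
        cfg = ShiftConfig(shift_unit, i, tuple(layout.names))
        shifted = shifted_position_null(dmps, cfg, layout)
        chroms = np.asarray([s.chromosome for s in shifted], dtype=object)
        pos = np.asarray([s.position for s in shifted], dtype=np.int64)
        vals = _statistics_for_positions(
            chroms, pos, gene_index, gwas_genes, universe,
            annotation, gwas_profile, tuple(requests),
        )
        for k, v in vals.items():
            draws[k].append(v)
    return {k: NullDistribution(k, np.asarray(v)) for k, v in draws.items()}


def expected_overlap_summary(
    observed: float, null: NullDistribution
) -> tuple[float, float]:
    """(expected value, p_diff): the null mean and the two-sided z-test
    of the observed statistic against it."""
    return null.mean, stats.z_test_vs_null(observed, null)
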