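"""Overlap statistics for GWAS/EWAS gene lists.

The central quantities are cross-product odds ratios over 2x2 tables:

* gene overlap — odds of a gene being identified by both studies over
  the odds of it being identified by the EWAS only;
* geneset enrichment — per geneset, the odds of a hit gene being a
  member over the odds of a non-hit gene being a member, yielding an
  enrichment profile whose rank correlation between two studies
  measures shared biology;
* direct geneset overlap — the same 2x2 machinery over the geneset
  universe, a geneset counting as "identified" when at least one hit
  gene belongs to it.

Zero cells are meaningful (an empty intersection prints OR = 0) and no
continuity correction is applied by default: downstream comparisons use
ranks, which zeros and infinities participate in naturally. Supporting
statistics: two-sided Fisher exact p, a z-test against a resampling
null, Benjamini-Hochberg FDR, and the rank (Mann-Whitney) AUC with a
DeLong confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .types import GenesetAnnotation, ValidationError


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a = in both lists, b = first only, c = second only,
    d = remainder of the universe."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def cross_product_or(a: float, b: float, c: float, d: float) -> float:
    """(a*d)/(b*c) with the 0 / +inf conventions for empty cells.

    When b*c = 0 the ratio is +inf for a non-empty intersection (one
    list contains the other with empty complement cells) and 0 for an
    empty one; this also resolves the 0/0 corner where both lists cover
    the whole universe.
    """
    num, den = a * d, b * c
    if den > 0:
        return num / den
    return np.inf if a > 0 else 0.0


@dataclass(frozen=True)
class OverlapResult:
    table: ContingencyTable
    odds_ratio: float
    fisher_p: float


def fisher_or(table: ContingencyTable) -> OverlapResult:
    """Cross-product odds ratio plus two-sided Fisher exact p-value."""
    if table.a + table.b < 1:
        raise ValidationError("first list is empty (a + b = 0)")
    odds = cross_product_or(table.a, table.b, table.c, table.d)
    _, p = sps.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative="two-sided"
    )
    return OverlapResult(table, odds, float(p))


def gene_overlap(ewas_genes: set, gwas_genes: set, universe: set) -> OverlapResult:
    """Overlap of two gene lists against a declared gene universe."""
    for name, genes in (("EWAS", ewas_genes), ("GWAS", gwas_genes)):
        stray = set(genes) - universe
        if stray:
            raise ValidationError(
                f"{name} gene(s) outside universe: {sorted(stray)[:5]}"
            )
    e, g = set(ewas_genes), set(gwas_genes)
    a = len(e & g)
    b = len(e - g)
    c = len(g - e)
    d = len(universe) - len(e | g)
    return fisher_or(ContingencyTable(a, b, c, d))


@dataclass
class EnrichmentProfile:
    """Per-geneset enrichment odds ratios for one study's hit genes."""

    study: str
    geneset_ids: list[str]
    scores: np.ndarray  # aligned with geneset_ids; 0/inf allowed
    hit_genes: set[str] = field(default_factory=set)
    a_counts: np.ndarray | None = None  # per-geneset |hits ∩ S| trace

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.geneset_ids, self.scores))

    def identified_sets(self) -> set[str]:
        """Genesets containing at least one hit gene (cell a > 0)."""
        if self.a_counts is not None:
            flags = np.asarray(self.a_counts) > 0
        else:  # score > 0 iff a > 0, outside degenerate 0/0 corners
            flags = np.asarray(self.scores) > 0
        return {gs for gs, f in zip(self.geneset_ids, flags) if f}


def enrichment_profile(
    hit_genes: set[str], annotation: GenesetAnnotation, study: str = ""
) -> EnrichmentProfile:
    """Enrichment odds ratio for every geneset in the annotation.

    For a geneset S and hit list H over universe U the 2x2 cells are
    a=|H∩S|, b=|H\\S|, c=|S\\H|, d=|U|-|H∪S|; the score is (a*d)/(b*c).
    Zero scores (no hit gene in the set) are expected and preserved.
    """
    hit_genes = set(hit_genes)
    if not hit_genes:
        raise ValidationError("empty hit-gene set")
    if not hit_genes <= annotation.universe:
        stray = sorted(hit_genes - annotation.universe)[:5]
        raise ValidationError(f"hit gene(s) outside universe: {stray}")
    mat, _ = annotation.membership_matrix()
    hit_idx = annotation.gene_indices(sorted(hit_genes))
    n_univ = len(annotation.universe)
    n_hits = len(hit_genes)
    set_sizes = mat.sum(axis=1)
    a = mat[:, hit_idx].sum(axis=1).astype(float)
    b = n_hits - a
    c = set_sizes - a
    d = n_univ - n_hits - set_sizes + a
    with np.errstate(divide="ignore", invalid="ignore"):
        num, den = a * d, b * c
        scores = np.where(den > 0, num / np.where(den > 0, den, 1.0),
                          np.where(a > 0, np.inf, 0.0))
    return EnrichmentProfile(
        study, annotation.geneset_ids, scores, hit_genes, a_counts=a
    )


def geneset_overlap(
    profile_a: EnrichmentProfile, profile_b: EnrichmentProfile
) -> OverlapResult:
    """Direct overlap of the genesets 'identified' by two studies.

    A geneset is identified when >= 1 hit gene is a member; the 2x2 is
    over the shared geneset universe.
    """
    if profile_a.geneset_ids != profile_b.geneset_ids:
        raise ValidationError("profiles computed over different geneset domains")
    ia, ib = profile_a.identified_sets(), profile_b.identified_sets()
    n = len(profile_a.geneset_ids)
    a = len(ia & ib)
    b = len(ia - ib)
    c = len(ib - ia)
    d = n - len(ia | ib)
    return fisher_or(ContingencyTable(a, b, c, d))


def enrichment_correlation(
    p1: EnrichmentProfile, p2: EnrichmentProfile
) -> float:
    """Spearman rank correlation between two enrichment profiles.

    Enrichment scores are heavily non-normal (many zeros, occasional
    infinities), so the association is measured on ranks of the log
    scores; log is monotone, hence the ranks of the raw scores are used
    directly, with zeros tied at the bottom and infinities at the top.
    """
    if p1.geneset_ids != p2.geneset_ids:
        raise ValidationError("profiles computed over different geneset domains")
    if len(p1.scores) < 3:
        raise ValidationError("need at least 3 genesets for a rank correlation")
    s1, s2 = np.asarray(p1.scores, float), np.asarray(p2.scores, float)
    if np.isnan(s1).any() or np.isnan(s2).any():
        raise ValidationError("profiles contain undefined (0/0) scores")
    if np.all(s1 == s1[0]) or np.all(s2 == s2[0]):
        raise ValidationError("zero variance in an enrichment profile")
    rho = sps.spearmanr(s1, s2).statistic
    return float(rho)


@dataclass
class NullDistribution:
    """Resampling draws of a statistic, summarised by mean and sd."""

    statistic_name: str
    draws: np.ndarray

    def __post_init__(self):
        self.draws = np.asarray(self.draws, dtype=float)

    @property
    def mean(self) -> float:
        return float(np.mean(self.draws))

    @property
    def sd(self) -> float:
        return float(np.std(self.draws, ddof=1)) if len(self.draws) > 1 else 0.0


def z_test_vs_null(observed: float, null: NullDistribution) -> float:
    """Two-sided z-test of an observed statistic against a resampling
    null: p = 2*Phi(-|observed - mean| / sd)."""
    if null.sd <= 0:
        raise ValidationError(
            f"degenerate null distribution for {null.statistic_name!r} (sd = 0)"
        )
    z = (observed - null.mean) / null.sd
    return float(2.0 * sps.norm.sf(abs(z)))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class AucResult:
    auc: float
    ci_low: float
    ci_high: float
    se: float


def rank_auc(scores, labels, ci: bool = True) -> AucResult:
    """Rank (Mann-Whitney) AUC: P(score1 > score0) + 0.5*P(tie).

    The 95% CI uses the DeLong placement-value variance, the standard
    distribution-free estimator. Infinite scores are fine (ranks).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels differ in length")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValidationError("both classes must be present")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    auc = (ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    if not ci:
        return AucResult(float(auc), np.nan, np.nan, np.nan)
    # DeLong: placement of each positive among negatives and vice versa
    v10 = (ranks[:m] - sps.rankdata(pos)) / n
    v01 = 1.0 - (ranks[m:] - sps.rankdata(neg)) / m
    if m < 2 or n < 2:
        warnings.warn("fewer than 2 observations in a class: CI degenerate")
        return AucResult(float(auc), np.nan, np.nan, np.nan)
    se = float(np.sqrt(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n))
    half = sps.norm.ppf(0.975) * se
    return AucResult(
        float(auc),
        float(max(0.0, auc - half)),
        float(min(1.0, auc + half)),
        se,
    )
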