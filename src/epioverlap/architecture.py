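"""Inferring genetic/epigenetic architecture from observed geneset overlap.

Given the empirically identified ("known") GWAS genes (KGG) and EWAS
genes (KEG) of a trait, each candidate architecture posits a total pool
of trait genes — causal and associated pools of equal size
``N_KTG x multiplier`` with ``N_KTG = N_KGG + N_KEG`` — and a
causal/associated overlap proportion. The known genes are embedded in
their respective pools, the remainder is filled from the gene universe,
and the observable study outcome is re-simulated many times: draw
N_KGG genes from the causal pool and N_KEG from the associated pool and
correlate their geneset-enrichment profiles. Scenarios whose simulated
correlation distribution is incompatible with the empirically observed
correlation (two-sided z-test, Benjamini-Hochberg FDR across the grid)
are flagged as unlikely architectures.

Overlap-proportion endpoints: 0 means the pools share only the forced
KGG ∩ KEG overlap; 1 means the only associated genes outside the causal
pool are the KEG not identified by the GWAS. Intermediate proportions
interpolate linearly over the feasible extra overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from . import stats
from .types import GenesetAnnotation, ValidationError, child_rng

MULTIPLIERS = (1, 2, 3, 5, 10, 20)
OVERLAP_PROPORTIONS = (0.0, 0.01, 0.1, 0.5, 1.0)


@dataclass(frozen=True)
class ArchScenario:
    n_kgg: int
    n_keg: int
    multiplier: int
    overlap_proportion: float
    reps: int = 1000

    def __post_init__(self):
        if self.n_kgg < 1 or self.n_keg < 1:
            raise ValidationError("need at least one known gene per study")
        if not (0.0 <= self.overlap_proportion <= 1.0):
            raise ValidationError("overlap_proportion must lie in [0, 1]")

    @property
    def n_ktg(self) -> int:
        return self.n_kgg + self.n_keg

    @property
    def pool_size(self) -> int:
        """Causal pool size = associated pool size = N_KTG x multiplier."""
        return self.n_ktg * self.multiplier

    @property
    def total_genes(self) -> int:
        """Total simulated trait genes (both pools, counting overlap twice)."""
        return 2 * self.pool_size


@dataclass
class ArchResult:
    scenario: ArchScenario
    simulated: np.ndarray
    empirical: float
    z_p: float
    fdr_q: float = float("nan")

    @property
    def rejected(self) -> bool:
        return self.fdr_q < 0.05


def target_overlap(scenario: ArchScenario, kgg: set, keg: set) -> int:
    """|causal ∩ associated| implied by the overlap proportion.

    At 0 the overlap is the forced |KGG ∩ KEG|; at 1 it is
    pool_size - |KEG \\ KGG| (associated \\ causal = KEG \\ KGG);
    intermediate proportions interpolate linearly and round to genes.
    """
    base = len(kgg & keg)
    max_overlap = scenario.pool_size - len(keg - kgg)
    if max_overlap < base:
        raise ValidationError(
            f"pool size {scenario.pool_size} cannot accommodate the known genes"
        )
    return base + round(scenario.overlap_proportion * (max_overlap - base))


def build_pools(
    kgg: set,
    keg: set,
    scenario: ArchScenario,
    universe: set,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Construct (causal pool, associated pool) for one scenario.

    KGG ⊆ causal and KEG ⊆ associated always hold; novel genes are
    sampled from the universe outside KGG ∪ KEG. Extra overlap beyond
    the forced KGG ∩ KEG is created by adding causal genes to the
    associated pool.
    """
    if not (kgg <= universe and keg <= universe):
        raise ValidationError("known genes must lie inside the gene universe")
    size = scenario.pool_size
    if len(kgg) > size:
        raise ValidationError(
            f"pool size {size} smaller than the {len(kgg)} known GWAS genes"
        )
    if len(keg) > size:
        raise ValidationError(
            f"pool size {size} smaller than the {len(keg)} known EWAS genes"
        )
    t = target_overlap(scenario, kgg, keg)
    base = len(kgg & keg)
    extra = t - base
    novel_universe = np.asarray(sorted(universe - kgg - keg))
    n_novel_causal = size - len(kgg)
    n_fill_assoc = size - len(keg) - extra
    if n_fill_assoc < 0:
        raise ValidationError(
            "target overlap exceeds the associated pool's free capacity"
        )
    if n_novel_causal + n_fill_assoc > len(novel_universe):
        raise ValidationError(
            f"universe too small: need {n_novel_causal + n_fill_assoc} novel "
            f"genes, have {len(novel_universe)}"
        )
    novel = rng.choice(
        novel_universe, size=n_novel_causal + n_fill_assoc, replace=False
    )
    causal = np.concatenate([np.asarray(sorted(kgg)), novel[:n_novel_causal]])
    # extra overlap genes: causal genes not already in KEG
    causal_not_keg = np.asarray(sorted(set(causal.tolist()) - keg))
    if extra > len(causal_not_keg):
        raise ValidationError("target overlap exceeds available causal genes")
    overlap_extra = rng.choice(causal_not_keg, size=extra, replace=False)
    associated = np.concatenate(
        [np.asarray(sorted(keg)), overlap_extra, novel[n_novel_causal:]]
    )
    assert len(causal) == size and len(associated) == size
    return causal, associated


def run_arch_scenario(
    scenario: ArchScenario,
    kgg: set,
    keg: set,
    annotation: GenesetAnnotation,
    empirical_rho: float,
    seed: int = 0,
) -> ArchResult:
    """Simulate one architecture scenario and test it against the
    empirically observed enrichment-score correlation.

    The pools are constructed once per scenario (they define the
    candidate architecture); each repetition re-draws the observable
    study outcome from them.
    """
    pool_rng = child_rng(seed, "arch_pools", scenario.multiplier,
                         scenario.overlap_proportion)
    causal, associated = build_pools(kgg, keg, scenario,
                                     annotation.universe, pool_rng)
    sims = np.empty(scenario.reps)
    for i in range(scenario.reps):
        rng = child_rng(seed, "arch", scenario.multiplier,
                        scenario.overlap_proportion, i)
        gwas = set(rng.choice(causal, size=scenario.n_kgg, replace=False))
        ewas = set(rng.choice(associated, size=scenario.n_keg, replace=False))
        pg = stats.enrichment_profile(gwas, annotation, study="gwas_sim")
        pe = stats.enrichment_profile(ewas, annotation, study="ewas_sim")
        sims[i] = stats.enrichment_correlation(pe, pg)
    null = stats.NullDistribution("enrichment_correlation", sims)
    z_p = stats.z_test_vs_null(empirical_rho, null)
    return ArchResult(scenario, sims, empirical_rho, z_p)


def default_grid(n_kgg: int, n_keg: int, reps: int = 1000) -> list[ArchScenario]:
    """Cartesian multiplier x overlap-proportion grid (30 scenarios)."""
    return [
        ArchScenario(n_kgg, n_keg, m, p, reps)
        for m, p in product(MULTIPLIERS, OVERLAP_PROPORTIONS)
    ]


def run_arch_grid(
    kgg: set,
    keg: set,
    annotation: GenesetAnnotation,
    empirical_rho: float,
    grid: list[ArchScenario] | None = None,
    seed: int = 0,
    reps: int = 1000,
) -> list[ArchResult]:
    """Run the scenario grid for one trait and attach BH-FDR q-values."""
    if grid is None:
        grid = default_grid(len(kgg), len(keg), reps)
    results = [
        run_arch_scenario(s, kgg, keg, annotation, empirical_rho, seed)
        for s in grid
    ]
    attach_fdr(results)
    return results


def attach_fdr(results: list[ArchResult]) -> None:
    """BH-FDR across a pooled list of scenario z-test p-values
    (pool across traits before calling when analysing several)."""
    qs = stats.bh_fdr([r.z_p for r in results])
    for r, q in zip(results, qs):
        r.fdr_q = float(q)


def results_table(results: list[ArchResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        s = r.scenario
        q25, q50, q75 = np.percentile(r.simulated, [25, 50, 75])
        rows.append({
            "multiplier": s.multiplier,
            "overlap_proportion": s.overlap_proportion,
            "total_genes": s.total_genes,
            "sim_median": q50,
            "sim_iqr_low": q25,
            "sim_iqr_high": q75,
            "empirical_rho": r.empirical,
            "z_p": r.z_p,
            "fdr_q": r.fdr_q,
            "rejected": r.rejected,
        })
    return pd.DataFrame(rows)
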