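"""Power to detect GWAS/EWAS overlap under known architectures.

Each scenario draws, many times over, a "GWAS gene" list (sampled only
from the causal pool) and an "EWAS gene" list in which a set proportion
of the genes are causal and the rest come from the associated pool.
EWAS power is operationalised as the number of associated genes the
study detects. Three overlap metrics are computed per draw — the gene
overlap odds ratio OR_g, the direct geneset overlap odds ratio OR_p,
and the enrichment-score rank correlation rho_p — and the ability of
each metric to discriminate a scenario with causal EWAS genes from the
matched scenario with none is summarised as a rank AUC with a DeLong
95% confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import stats
from .types import GenesetAnnotation, ValidationError, child_rng

METRICS = ("or_g", "or_p", "rho_p")

DEFAULT_PROPS = (0.0, 0.05, 1.0)
DEFAULT_N_ASSOC = (50, 100, 500)
DEFAULT_POWERS = (0.2, 0.5, 1.0)


def default_grid(
    n_gwas_genes: int = 100,
    props=DEFAULT_PROPS,
    n_assoc=DEFAULT_N_ASSOC,
    powers=DEFAULT_POWERS,
    annotation_id: str = "default",
    iterations: int = 1000,
) -> list["PowerScenario"]:
    """Default scenario grid: every (prop, Assoc genes, power) combination,
    with the prop = 0 null twin included for each parameter pair."""
    grid = []
    for na in n_assoc:
        for pw in powers:
            for pr in props:
                grid.append(PowerScenario(
                    n_gwas_genes=n_gwas_genes, n_assoc_detected=na,
                    ewas_power=pw, prop_causal_ewas=pr,
                    annotation_id=annotation_id, iterations=iterations,
                ))
    return grid


def default_pools(
    universe: list[str],
    n_causal: int = 1000,
    n_assoc: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint causal and associated pools drawn from the gene universe."""
    ids = np.asarray(sorted(universe))
    if n_causal + n_assoc > len(ids):
        raise ValidationError("pools exceed universe size")
    rng = child_rng(seed, "power_pools")
    drawn = rng.choice(ids, size=n_causal + n_assoc, replace=False)
    return drawn[:n_causal], drawn[n_causal:]


@dataclass(frozen=True)
class PowerScenario:
    n_gwas_genes: int
    n_assoc_detected: int  # "Assoc genes": associated genes detectable at full power
    ewas_power: float
    prop_causal_ewas: float
    annotation_id: str = "default"
    iterations: int = 1000

    def __post_init__(self):
        if not (0.0 <= self.ewas_power <= 1.0):
            raise ValidationError("ewas_power must lie in [0, 1]")
        if not (0.0 <= self.prop_causal_ewas <= 1.0):
            raise ValidationError("prop_causal_ewas must lie in [0, 1]")

    @property
    def n_ewas_detected(self) -> int:
        """Detected EWAS genes: power x the detectable associated genes."""
        return round(self.ewas_power * self.n_assoc_detected)

    @property
    def n_causal_in_ewas(self) -> int:
        return round(self.prop_causal_ewas * self.n_ewas_detected)

    def null_twin(self) -> "PowerScenario":
        return replace(self, prop_causal_ewas=0.0)


@dataclass
class ScenarioDraw:
    gwas_genes: set
    ewas_genes: set
    or_g: float
    or_p: float
    rho_p: float


@dataclass
class PowerResult:
    scenario: PowerScenario
    auc: dict[str, stats.AucResult]
    draws: pd.DataFrame | None = None


def draw_scenario(
    scenario: PowerScenario,
    causal_pool: np.ndarray,
    assoc_pool: np.ndarray,
    annotation: GenesetAnnotation,
    rng: np.random.Generator,
    universe: set | None = None,
) -> ScenarioDraw:
    """One simulation draw: sample the two gene lists and compute the
    three overlap metrics.

    The EWAS draw contains exactly ``round(prop_causal_ewas x n)``
    causal-pool genes; the remainder is sampled from the associated
    pool excluding the causal pool, keeping the composition exact.
    """
    causal_pool = np.asarray(causal_pool)
    assoc_pool = np.asarray(assoc_pool)
    universe = universe if universe is not None else annotation.universe
    n_ewas = scenario.n_ewas_detected
    n_causal = scenario.n_causal_in_ewas
    n_assoc = n_ewas - n_causal
    assoc_only = np.setdiff1d(assoc_pool, causal_pool, assume_unique=False)
    if scenario.n_gwas_genes > len(causal_pool) or n_causal > len(causal_pool):
        raise ValidationError("requested sample exceeds causal pool")
    if n_assoc > len(assoc_only):
        raise ValidationError("requested sample exceeds associated-only pool")
    gwas = set(rng.choice(causal_pool, size=scenario.n_gwas_genes, replace=False))
    ewas = set(rng.choice(causal_pool, size=n_causal, replace=False))
    ewas |= set(rng.choice(assoc_only, size=n_assoc, replace=False))
    gov = stats.gene_overlap(ewas, gwas, universe)
    pe = stats.enrichment_profile(ewas, annotation, study="ewas")
    pg = stats.enrichment_profile(gwas, annotation, study="gwas")
    pov = stats.geneset_overlap(pe, pg)
    rho = stats.enrichment_correlation(pe, pg)
    return ScenarioDraw(gwas, ewas, gov.odds_ratio, pov.odds_ratio, rho)


def _scenario_metric_draws(
    scenario: PowerScenario,
    causal_pool,
    assoc_pool,
    annotation,
    seed: int,
    reps: int,
    universe=None,
) -> pd.DataFrame:
    rows = []
    for i in range(reps):
        # annotation_id is deliberately absent from the stream keys so that
        # annotation methods are compared on identical gene draws
        rng = child_rng(seed, "power",
                        scenario.prop_causal_ewas, scenario.ewas_power,
                        scenario.n_assoc_detected, scenario.n_gwas_genes, i)
        d = draw_scenario(scenario, causal_pool, assoc_pool, annotation, rng, universe)
        rows.append((d.or_g, d.or_p, d.rho_p))
    return pd.DataFrame(rows, columns=list(METRICS))


def run_power_grid(
    grid: list[PowerScenario],
    causal_pool,
    assoc_pool,
    annotation: GenesetAnnotation,
    seed: int = 0,
    reps: int | None = None,
    keep_draws: bool = False,
    universe=None,
) -> list[PowerResult]:
    """AUC discrimination of each non-null scenario from its null twin.

    Every scenario with prop_causal_ewas > 0 must have its matched
    prop = 0 twin in the grid (same remaining parameters). Per metric,
    the 2 x reps metric values are scored against the scenario
    indicator with the rank AUC.
    """
    by_key = {
        (s.annotation_id, s.n_gwas_genes, s.n_assoc_detected, s.ewas_power,
         s.prop_causal_ewas): s
        for s in grid
    }
    results = []
    cache: dict[tuple, pd.DataFrame] = {}

    def draws_for(s: PowerScenario, n: int) -> pd.DataFrame:
        key = (s.annotation_id, s.n_gwas_genes, s.n_assoc_detected,
               s.ewas_power, s.prop_causal_ewas, n)
        if key not in cache:
            cache[key] = _scenario_metric_draws(
                s, causal_pool, assoc_pool, annotation, seed, n, universe
            )
        return cache[key]

    for s in grid:
        if s.prop_causal_ewas == 0.0:
            continue
        twin_key = (s.annotation_id, s.n_gwas_genes, s.n_assoc_detected,
                    s.ewas_power, 0.0)
        if twin_key not in by_key:
            raise ValidationError(
                f"scenario {s} lacks its matched prop_causal_ewas=0 twin"
            )
        n = reps if reps is not None else s.iterations
        if n == 1:
            warnings.warn("reps=1: AUC defined but its CI is degenerate")
        alt = draws_for(s, n)
        null = draws_for(by_key[twin_key], n)
        auc = {}
        for metric in METRICS:
            scores = np.concatenate([alt[metric], null[metric]])
            labels = np.concatenate([np.ones(len(alt)), np.zeros(len(null))])
            auc[metric] = stats.rank_auc(scores, labels, ci=(n > 1))
        results.append(
            PowerResult(s, auc, draws=alt if keep_draws else None)
        )
    return results


def results_table(results: list[PowerResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        s = r.scenario
        row = {
            "annotation_id": s.annotation_id,
            "n_gwas_genes": s.n_gwas_genes,
            "n_assoc_detected": s.n_assoc_detected,
            "ewas_power": s.ewas_power,
            "prop_causal_ewas": s.prop_causal_ewas,
        }
        for metric, a in r.auc.items():
            row[f"auc_{metric}"] = a.auc
            row[f"auc_{metric}_lo"] = a.ci_low
            row[f"auc_{metric}_hi"] = a.ci_high
        rows.append(row)
    return pd.DataFrame(rows)


def compare_annotations(results: list[PowerResult]) -> pd.DataFrame:
    """Rank annotation methods by per-scenario AUC, with deltas to the
    best annotation for each scenario; no significance claims beyond
    the attached confidence intervals."""
    df = results_table(results)
    if df.empty:
        raise ValidationError("no results to compare")
    scen_cols = ["n_gwas_genes", "n_assoc_detected", "ewas_power", "prop_causal_ewas"]
    grids = {aid: g[scen_cols].sort_values(scen_cols).reset_index(drop=True)
             for aid, g in df.groupby("annotation_id")}
    ref = next(iter(grids.values()))
    for aid, g in grids.items():
        if not g.equals(ref):
            raise ValidationError(f"annotation {aid!r} ran a different scenario grid")
    out = []
    for _, scen in ref.iterrows():
        mask = (df[scen_cols] == scen.values).all(axis=1)
        sub = df[mask]
        for metric in METRICS:
            best = sub[f"auc_{metric}"].max()
            for _, row in sub.iterrows():
                out.append({
                    **scen.to_dict(),
                    "metric": metric,
                    "annotation_id": row["annotation_id"],
                    "auc": row[f"auc_{metric}"],
                    "delta_to_best": row[f"auc_{metric}"] - best,
                    "ci_low": row[f"auc_{metric}_lo"],
                    "ci_high": row[f"auc_{metric}_hi"],
                })
    return pd.DataFrame(out).sort_values(
        scen_cols + ["metric", "auc"], ascending=[True] * len(scen_cols) + [True, False]
    ).reset_index(drop=True)
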