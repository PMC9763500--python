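"""Cross-study comparison of geneset enrichment profiles.

Given enrichment profiles for many studies (GWAS and EWAS of various
traits) over a shared geneset domain, compute all pairwise Spearman
correlations, then test each pair's correlation against the grand mean
of all pairwise correlations (one-sided z using the empirical SD of the
pairwise correlations), with Benjamini-Hochberg FDR across pairs. The
question answered: are study pairs of a given kind (GWAS-GWAS,
GWAS-EWAS, EWAS-EWAS) more concordant than the average pair?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import EnrichmentProfile, bh_fdr, enrichment_correlation
from .types import ValidationError


@dataclass
class CorrelationMatrix:
    labels: list[str]
    types: list[str]  # {"gwas", "ewas"} per study
    values: np.ndarray  # symmetric, unit diagonal

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValidationError("correlation matrix must be symmetric")
        self.values = v

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def grand_mean(self) -> float:
        return float(np.mean(self.upper_triangle()))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def pairwise_correlations(
    profiles: list[EnrichmentProfile], types: list[str] | None = None
) -> CorrelationMatrix:
    """All unordered pairwise enrichment-score correlations."""
    if len(profiles) < 2:
        raise ValidationError("need at least two profiles")
    domain = profiles[0].geneset_ids
    for p in profiles[1:]:
        if p.geneset_ids != domain:
            raise ValidationError(
                f"profile {p.study!r} uses a different geneset domain"
            )
    n = len(profiles)
    if types is None:
        types = ["gwas"] * n
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            rho = enrichment_correlation(profiles[i], profiles[j])
            mat[i, j] = mat[j, i] = rho
    return CorrelationMatrix([p.study for p in profiles], list(types), mat)


def _pair_group(t1: str, t2: str) -> str:
    return "-".join(sorted([t1, t2]))


def group_mean_tests(matrix: CorrelationMatrix) -> pd.DataFrame:
    """Per pair: one-sided z-test of its correlation exceeding the grand
    mean, using the empirical SD of all pairwise correlations; BH-FDR
    across pairs. Columns: pair, correlation, group, z_p, fdr_q."""
    corrs = matrix.upper_triangle()
    if len(corrs) < 3:
        raise ValidationError("need at least 3 pairs")
    mean = float(np.mean(corrs))
    sd = float(np.std(corrs, ddof=1))
    if sd <= 0:
        raise ValidationError("degenerate pairwise-correlation SD")
    rows = []
    n = len(matrix.labels)
    for i in range(n):
        for j in range(i + 1, n):
            r = matrix.values[i, j]
            z = (r - mean) / sd
            rows.append({
                "study_a": matrix.labels[i],
                "study_b": matrix.labels[j],
                "correlation": r,
                "group": _pair_group(matrix.types[i], matrix.types[j]),
                "z_p": float(sps.norm.sf(z)),
            })
    df = pd.DataFrame(rows)
    df["fdr_q"] = bh_fdr(df["z_p"].to_numpy())
    return df


def group_summary(pairs: pd.DataFrame) -> pd.DataFrame:
    """Mean correlation and FDR<0.05 count per pair group."""
    return (
        pairs.groupby("group")
        .agg(
            n_pairs=("correlation", "size"),
            mean_correlation=("correlation", "mean"),
            n_above_mean_fdr05=("fdr_q", lambda q: int((q < 0.05).sum())),
        )
        .reset_index()
    )
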