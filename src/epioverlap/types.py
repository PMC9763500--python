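"""Shared domain types for GWAS/EWAS overlap analyses.

The objects here are deliberately thin: a genome coordinate frame
(:class:`GenomeLayout`), gene and site records, a study's significant
hits (:class:`StudyHits`), a bidirectional gene/geneset annotation
(:class:`GenesetAnnotation`) and the run configuration. All coordinates
are 0-based, half-open; readers convert 1-based input on the way in.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GWAS_P_DEFAULT = 5e-8
EWAS_P_DEFAULT = 1e-7
REGION_P_DEFAULT = 1e-5
REGION_WIDTH_DEFAULT = 500_000


class FormatError(ValueError):
    """An input file violates its declared format."""


class ValidationError(ValueError):
    """Semantically invalid input (coordinates, counts, thresholds...)."""


def child_rng(seed: int, *keys) -> np.random.Generator:
    """Derive an independent, reproducible random stream.

    Every stochastic stage derives its generator from the run seed plus
    stage-identifying keys (stage name, scenario index, iteration), so
    any scenario can be re-run in isolation with identical draws.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        entropy.append(zlib.crc32(str(k).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths; the coordinate frame for binning,
    mapping and null resampling. The declared order is the wrap-around
    order used by the shifted-position null (last chromosome wraps to the
    first)."""

    chromosomes: tuple[tuple[str, int], ...]
    build_label: str = "synthetic"

    def __post_init__(self):
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names in layout")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length")

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def lengths(self) -> np.ndarray:
        return np.asarray([l for _, l in self.chromosomes], dtype=np.int64)

    @property
    def total_length(self) -> int:
        return int(self.lengths.sum())

    def length_of(self, chromosome: str) -> int:
        for name, length in self.chromosomes:
            if name == chromosome:
                return length
        raise KeyError(chromosome)

    def offsets(self) -> dict[str, int]:
        """Start offset of each chromosome on the concatenated genome."""
        out, cum = {}, 0
        for name, length in self.chromosomes:
            out[name] = cum
            cum += length
        return out


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chromosome: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    biotype: str = "protein_coding"  # {"protein_coding", "other"}

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.gene_id!r}: start {self.start} >= end {self.end}"
            )


@dataclass(frozen=True)
class SiteRecord:
    """A measured site: CpG probe or genetic variant."""

    site_id: str
    chromosome: str
    position: int  # 0-based
    p_value: float
    effect: float | None = None

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(
                f"site {self.site_id!r}: p-value {self.p_value} outside (0, 1]"
            )


@dataclass
class StudyHits:
    """A study's significant sites after p-value thresholding."""

    trait: str
    study_type: str  # {"gwas", "ewas"}
    sites: list[SiteRecord]
    threshold: float
    sample_size: int | None = None

    def __post_init__(self):
        if self.study_type not in ("gwas", "ewas"):
            raise ValidationError(f"unknown study type {self.study_type!r}")
        for s in self.sites:
            if s.p_value >= self.threshold:
                raise ValidationError(
                    f"site {s.site_id!r} has p={s.p_value} >= threshold {self.threshold}"
                )

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": [s.site_id for s in self.sites],
                "chromosome": [s.chromosome for s in self.sites],
                "position": np.asarray(
                    [s.position for s in self.sites], dtype=np.int64
                ),
                "p_value": [s.p_value for s in self.sites],
                "effect": [s.effect for s in self.sites],
            }
        )

    @staticmethod
    def default_threshold(study_type: str) -> float:
        return GWAS_P_DEFAULT if study_type == "gwas" else EWAS_P_DEFAULT


class GenesetAnnotation:
    """Bidirectional gene <-> geneset map over a declared gene universe.

    ``sets`` maps geneset id to member genes; ``inverse`` is its exact
    transpose. Genesets may only contain universe genes. A dense boolean
    membership matrix is built lazily for vectorised enrichment scoring.
    """

    def __init__(
        self,
        sets: dict[str, set[str]],
        universe: set[str] | None = None,
        descriptions: dict[str, str] | None = None,
    ):
        self.sets = {k: set(v) for k, v in sets.items()}
        members = set().union(*self.sets.values()) if self.sets else set()
        if universe is None:
            universe = members
        elif not members <= universe:
            missing = sorted(members - universe)[:5]
            raise ValidationError(f"geneset members outside universe: {missing}")
        self.universe = set(universe)
        self.descriptions = dict(descriptions or {})
        self.inverse: dict[str, set[str]] = {}
        for gs_id, genes in self.sets.items():
            for g in genes:
                self.inverse.setdefault(g, set()).add(gs_id)
        self._index: dict[str, int] | None = None
        self._matrix: np.ndarray | None = None
        self._set_ids: list[str] | None = None

    @property
    def geneset_ids(self) -> list[str]:
        if self._set_ids is None:
            self._set_ids = sorted(self.sets)
        return self._set_ids

    def _build_matrix(self) -> None:
        genes = sorted(self.universe)
        self._index = {g: i for i, g in enumerate(genes)}
        mat = np.zeros((len(self.geneset_ids), len(genes)), dtype=bool)
        for row, gs_id in enumerate(self.geneset_ids):
            idx = [self._index[g] for g in self.sets[gs_id]]
            mat[row, idx] = True
        self._matrix = mat

    def membership_matrix(self) -> tuple[np.ndarray, dict[str, int]]:
        """(genesets x universe-genes) boolean matrix and gene index."""
        if self._matrix is None:
            self._build_matrix()
        return self._matrix, self._index

    def gene_indices(self, genes) -> np.ndarray:
        if self._index is None:
            self._build_matrix()
        try:
            return np.asarray([self._index[g] for g in genes], dtype=np.intp)
        except KeyError as e:
            raise ValidationError(f"gene {e.args[0]!r} not in annotation universe")

    def restrict_universe(self, genes: set[str]) -> "GenesetAnnotation":
        """Annotation over ``universe ∩ genes`` (e.g. protein-coding only)."""
        keep = self.universe & set(genes)
        return GenesetAnnotation(
            {k: v & keep for k, v in self.sets.items()},
            universe=keep,
            descriptions=self.descriptions,
        )


@dataclass
class RunConfig:
    """Global knobs shared by all pipeline stages."""

    rng_seed: int = 0
    gwas_p: float = GWAS_P_DEFAULT
    ewas_p: float = EWAS_P_DEFAULT
    region_p: float = REGION_P_DEFAULT
    region_width: int = REGION_WIDTH_DEFAULT
    universe_mode: str = "all_genes"  # or "protein_coding"
    resample_reps: int = 1000

    def __post_init__(self):
        if self.region_width <= 0:
            raise ValidationError("region_width must be positive")
        if self.resample_reps < 1:
            raise ValidationError("resample_reps must be >= 1")
        if self.universe_mode not in ("all_genes", "protein_coding"):
            raise ValidationError(f"unknown universe_mode {self.universe_mode!r}")


def genes_by_chromosome(genes: list[GeneRecord]) -> dict[str, dict[str, np.ndarray]]:
    """Group gene records into per-chromosome coordinate arrays."""
    out: dict[str, dict[str, list]] = {}
    for g in genes:
        d = out.setdefault(g.chromosome, {"gene_id": [], "start": [], "end": []})
        d["gene_id"].append(g.gene_id)
        d["start"].append(g.start)
        d["end"].append(g.end)
    return {
        chrom: {
            "gene_id": np.asarray(d["gene_id"], dtype=object),
            "start": np.asarray(d["start"], dtype=np.int64),
            "end": np.asarray(d["end"], dtype=np.int64),
        }
        for chrom, d in out.items()
    }


def validate_genes(genes: list[GeneRecord], layout: GenomeLayout) -> None:
    """Check gene uniqueness and containment within the layout."""
    seen = set()
    lengths = dict(layout.chromosomes)
    for g in genes:
        if g.gene_id in seen:
            raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
        if g.chromosome not in lengths:
            raise ValidationError(
                f"gene {g.gene_id!r} on unknown chromosome {g.chromosome!r}"
            )
        if g.end > lengths[g.chromosome]:
            raise ValidationError(
                f"gene {g.gene_id!r} extends past end of {g.chromosome}"
            )
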