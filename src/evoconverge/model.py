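"""Shared data model for the experimental-evolution analysis pipeline.

All genomic coordinates are 1-based inclusive (the convention of GFF3 and of
the resequencing caller whose tabular output the pipeline consumes).
bedGraph's 0-based half-open intervals are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGT")

#: Effect classes tracked in mutation count tables.
COUNT_CLASSES = ("nonsynonymous", "synonymous", "nonsense", "promoter", "indel")


class MutationType(str, Enum):
    SNP = "SNP"
    INSERTION = "insertion"
    DELETION = "deletion"
    OTHER = "other"


class AssignmentKind(str, Enum):
    CODING = "coding"
    PROMOTER = "promoter"
    INTERGENIC = "intergenic"
    INTRON = "intron"


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval on a replicon, optionally carrying its CDS sequence.

    ``start``/``end`` are 1-based inclusive. ``cds_sequence`` is given on the
    gene's own strand (5'->3') and must cover the full interval when present.
    """

    gene_id: str
    element_id: str
    start: int
    end: int
    strand: str = "+"
    is_coding: bool = True
    cds_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start ({self.start}) > end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.cds_sequence is not None:
            if len(self.cds_sequence) != self.length:
                raise ValueError(
                    f"gene {self.gene_id}: CDS length {len(self.cds_sequence)} "
                    f"!= interval length {self.length}"
                )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def promoter_interval(self, window: int = 50) -> tuple[int, int]:
        """1-based inclusive interval immediately upstream of the start codon."""
        if self.strand == "+":
            return (self.start - window, self.start - 1)
        return (self.end + 1, self.end + window)

    def in_promoter(self, position: int, window: int = 50) -> bool:
        lo, hi = self.promoter_interval(window)
        return lo <= position <= hi


@dataclass
class MutationRecord:
    """One polymorphism call in one evolved lineage."""

    lineage_id: str
    element_id: str
    position: int
    ref_allele: str
    alt_allele: str
    mut_type: MutationType = MutationType.SNP
    frequency: float = 1.0
    assigned_gene: Optional[str] = None
    assignment_kind: Optional[AssignmentKind] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mut_type = MutationType(self.mut_type)
        if self.assignment_kind is not None:
            self.assignment_kind = AssignmentKind(self.assignment_kind)
        if not (0.0 <= self.frequency <= 1.0):
            raise ValueError(
                f"frequency {self.frequency} outside [0, 1] at "
                f"{self.element_id}:{self.position}"
            )
        if self.mut_type is MutationType.SNP:
            if (
                len(self.ref_allele) != 1
                or len(self.alt_allele) != 1
                or self.ref_allele == self.alt_allele
            ):
                raise ValueError(
                    f"SNP at {self.element_id}:{self.position} must have single, "
                    f"distinct ref/alt (got {self.ref_allele!r}->{self.alt_allele!r})"
                )

    def key(self) -> tuple:
        """Identity of the call irrespective of lineage (for ancestral removal)."""
        return (self.element_id, self.position, self.alt_allele, self.mut_type)


@dataclass(frozen=True)
class LineageMeta:
    lineage_id: str
    species: str
    treatment: str
    replicate: int
    partner: Optional[str] = None


class CountTable:
    """Genes x lineages mutation counts, stratified by effect class.

    Wraps one integer DataFrame per class in :data:`COUNT_CLASSES`, all with
    identical row (gene) and column (lineage) indexes.
    """

    def __init__(self, matrices: Mapping[str, pd.DataFrame]):
        if not matrices:
            raise ValueError("CountTable needs at least one class matrix")
        first = next(iter(matrices.values()))
        for cls, mat in matrices.items():
            if not mat.index.equals(first.index) or not mat.columns.equals(
                first.columns
            ):
                raise ValueError(f"class {cls!r} matrix shape/labels mismatch")
            if (mat.to_numpy() < 0).any():
                raise ValueError(f"negative counts in class {cls!r}")
        self._matrices = {cls: mat.astype(int) for cls, mat in matrices.items()}

    @classmethod
    def empty(
        cls, genes: Sequence[str], lineages: Sequence[str], classes=COUNT_CLASSES
    ) -> "CountTable":
        zero = pd.DataFrame(0, index=list(genes), columns=list(lineages), dtype=int)
        return cls({c: zero.copy() for c in classes})

    @property
    def genes(self) -> list[str]:
        return list(next(iter(self._matrices.values())).index)

    @property
    def lineages(self) -> list[str]:
        return list(next(iter(self._matrices.values())).columns)

    @property
    def classes(self) -> list[str]:
        return list(self._matrices)

    def matrix(self, effect_class: str) -> pd.DataFrame:
        return self._matrices[effect_class]

    def combined(self, classes: Iterable[str]) -> pd.DataFrame:
        """Element-wise sum of the requested class matrices."""
        classes = list(classes)
        out = self._matrices[classes[0]].copy()
        for c in classes[1:]:
            out = out + self._matrices[c]
        return out

    def increment(self, effect_class: str, gene_id: str, lineage_id: str, by=1):
        self._matrices[effect_class].loc[gene_id, lineage_id] += by

    def subset_lineages(self, lineages: Sequence[str]) -> "CountTable":
        return CountTable(
            {c: m.loc[:, list(lineages)] for c, m in self._matrices.items()}
        )


@dataclass
class CoverageTrack:
    """Per-position read depth for one replicon in one lineage.

    ``depth[i]`` is the depth at 1-based position ``i + 1``; the array spans
    the whole replicon (gaps filled with zero at read time).
    """

    lineage_id: str
    element_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1:
            raise ValueError("depth must be one-dimensional")
        if (self.depth < 0).any():
            raise ValueError("negative depth values")

    @property
    def length(self) -> int:
        return self.depth.size

    def depth_at(self, position: int) -> float:
        if not (1 <= position <= self.length):
            raise KeyError(
                f"position {position} outside {self.element_id} "
                f"(length {self.length})"
            )
        return float(self.depth[position - 1])

    def region(self, start: int, end: int) -> np.ndarray:
        """Depths over a 1-based inclusive interval."""
        if start < 1 or end > self.length or start > end:
            raise ValueError(f"bad region {start}-{end} on {self.element_id}")
        return self.depth[start - 1 : end]


@dataclass
class GrowthSeries:
    """Cell-density time series across serial transfers for one lineage.

    Times are in hours; densities in cells/ml. ``transfer_times_h`` mark the
    moments at which the culture was diluted by ``dilution_factor``.
    """

    lineage_id: str
    times_h: np.ndarray
    densities: np.ndarray
    transfer_times_h: np.ndarray
    dilution_factor: float

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        self.transfer_times_h = np.asarray(self.transfer_times_h, dtype=float)
        if self.times_h.shape != self.densities.shape:
            raise ValueError("times and densities differ in length")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.densities <= 0):
            raise ValueError("densities must be positive")
        if self.dilution_factor <= 1:
            raise ValueError("dilution factor must exceed 1")

    @property
    def n_transfers(self) -> int:
        return self.transfer_times_h.size

    def window(self, transfer_index: int) -> tuple[np.ndarray, np.ndarray]:
        """Observations within transfer window ``transfer_index`` (0-based).

        Window k spans (transfer_time[k], transfer_time[k+1]]; the final
        window is open-ended.
        """
        if not (0 <= transfer_index < self.n_transfers):
            raise IndexError(f"transfer index {transfer_index} out of range")
        t0 = self.transfer_times_h[transfer_index]
        t1 = (
            self.transfer_times_h[transfer_index + 1]
            if transfer_index + 1 < self.n_transfers
            else np.inf
        )
        mask = (self.times_h > t0) & (self.times_h <= t1)
        return self.times_h[mask], self.densities[mask]
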