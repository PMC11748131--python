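"""Variant-curation rules applied to raw polymorphism calls.

The curation chain removes, in a fixed order:

1. calls at reference-discrepancy loci (apparent variants present at 100%
   in a re-assembly of the ancestor against the published reference, i.e.
   artifacts of the reference sequence rather than evolution);
2. calls at ancestrally heterozygous loci that did not fix in the evolved
   lineage (loss-of-heterozygosity candidates are kept only once fixed);
3. calls at positions with insufficient read depth;
4. calls shared by 100% of an organism's replicate lineages (ancestral
   mutations that predate the experiment);
5. calls below the per-population frequency cutoff.

The order is recorded in the report for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .model import CoverageTrack, MutationRecord

CURATION_ORDER = (
    "reference_discrepancy",
    "heterozygous_nonfixed",
    "low_coverage",
    "ancestral",
    "below_frequency_cutoff",
)


@dataclass(frozen=True)
class ReferenceVariantSet:
    """Loci flagged by re-assembling the ancestor against its reference.

    ``fixed_discrepancies`` were at 100% frequency in the ancestral
    re-assembly (reference errors); ``heterozygous_loci`` were at
    intermediate frequency (ancestrally heterozygous positions).
    """

    fixed_discrepancies: frozenset  # of (element_id, position, alt)
    heterozygous_loci: frozenset  # of (element_id, position)

    def __post_init__(self) -> None:
        fixed_pos = {(e, p) for e, p, _ in self.fixed_discrepancies}
        if fixed_pos & set(self.heterozygous_loci):
            raise ValueError(
                "fixed-discrepancy and heterozygous loci overlap on (element, position)"
            )


@dataclass
class CurationReport:
    input_count: int = 0
    removed: dict = field(default_factory=lambda: {r: 0 for r in CURATION_ORDER})
    order: tuple = CURATION_ORDER

    @property
    def surviving(self) -> int:
        return self.input_count - sum(self.removed.values())

    def as_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "removed": dict(self.removed),
            "surviving": self.surviving,
            "order": list(self.order),
        }


def remove_ancestral(
    mutations: Sequence[MutationRecord],
) -> tuple[list[MutationRecord], list[MutationRecord]]:
    """Drop calls present in 100% of the organism's replicate lineages.

    A call is keyed by (element, position, alt, type); if every lineage in
    the input carries it, it is treated as ancestral and removed everywhere.
    """
    if not mutations:
        return [], []
    lineages = {m.lineage_id for m in mutations}
    if len(lineages) < 2:
        raise ValueError(
            "ancestral removal needs calls from >= 2 lineages of one organism"
        )
    carriers: dict[tuple, set] = {}
    for m in mutations:
        carriers.setdefault(m.key(), set()).add(m.lineage_id)
    ancestral_keys = {k for k, ls in carriers.items() if ls == lineages}
    kept = [m for m in mutations if m.key() not in ancestral_keys]
    removed = [m for m in mutations if m.key() in ancestral_keys]
    return kept, removed


def mask_low_coverage(
    mutations: Sequence[MutationRecord],
    coverage: Mapping[tuple[str, str], CoverageTrack],
    min_depth: float = 5,
) -> tuple[list[MutationRecord], list[MutationRecord]]:
    """Drop calls whose position has depth < ``min_depth`` (boundary kept).

    ``coverage`` maps (lineage_id, element_id) to the lineage's track.
    """
    kept, removed = [], []
    for m in mutations:
        track = coverage.get((m.lineage_id, m.element_id))
        if track is None:
            raise KeyError(
                f"no coverage track for lineage {m.lineage_id!r}, "
                f"element {m.element_id!r}"
            )
        if track.depth_at(m.position) < min_depth:
            removed.append(m)
        else:
            kept.append(m)
    return kept, removed


def resolve_heterozygous(
    mutations: Sequence[MutationRecord],
    ref_set: ReferenceVariantSet,
    fixed_threshold: float = 0.99,
) -> tuple[list[MutationRecord], list[MutationRecord], list[MutationRecord]]:
    """Apply the reference-discrepancy and heterozygous-locus rules.

    Returns (kept, removed_discrepancy, removed_het_nonfixed). Calls at
    fixed-discrepancy loci are always removed; calls at ancestrally
    heterozygous loci survive only once fixed (frequency >= threshold).
    """
    kept, removed_disc, removed_het = [], [], []
    for m in mutations:
        if (m.element_id, m.position, m.alt_allele) in ref_set.fixed_discrepancies:
            removed_disc.append(m)
        elif (m.element_id, m.position) in ref_set.heterozygous_loci:
            if m.frequency >= fixed_threshold:
                kept.append(m)
            else:
                removed_het.append(m)
        else:
            kept.append(m)
    return kept, removed_disc, removed_het


def apply_frequency_cutoff(
    mutations: Sequence[MutationRecord], cutoff: float = 0.05
) -> tuple[list[MutationRecord], list[MutationRecord]]:
    """Drop calls below the per-population frequency cutoff (>= kept)."""
    kept = [m for m in mutations if m.frequency >= cutoff]
    removed = [m for m in mutations if m.frequency < cutoff]
    return kept, removed


def curate(
    mutations: Sequence[MutationRecord],
    ref_set: Optional[ReferenceVariantSet] = None,
    coverage: Optional[Mapping[tuple[str, str], CoverageTrack]] = None,
    min_depth: float = 5,
    fixed_threshold: float = 0.99,
    freq_cutoff: float = 0.05,
    remove_ancestral_calls: bool = True,
) -> tuple[list[MutationRecord], CurationReport]:
    """Run the full curation chain in its fixed order and report counts."""
    report = CurationReport(input_count=len(mutations))
    current = list(mutations)
    if ref_set is not None:
        current, disc, het = resolve_heterozygous(current, ref_set, fixed_threshold)
        report.removed["reference_discrepancy"] = len(disc)
        report.removed["heterozygous_nonfixed"] = len(het)
    if coverage is not None:
        current, low = mask_low_coverage(current, coverage, min_depth)
        report.removed["low_coverage"] = len(low)
    if remove_ancestral_calls and current:
        current, anc = remove_ancestral(current)
        report.removed["ancestral"] = len(anc)
    current, below = apply_frequency_cutoff(current, freq_cutoff)
    report.removed["below_frequency_cutoff"] = len(below)
    return current, report
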