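"""Codon-aware SNP effect classification and neutral expectations.

Effects are determined by translating the reference and mutated codons under
an (injectable) genetic code. Expected synonymous/nonsynonymous site counts
follow the classic enumeration approach: each codon position contributes the
fraction of its three possible substitutions that are synonymous. These site
counts are the denominators that put the pN/pS-style ratio on a scale where
neutral evolution gives 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Data import CodonTable

from .model import GeneAnnotation

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})
#: The 12 ordered substitution types.
SUBSTITUTIONS = tuple(
    (r, a) for r in BASES for a in BASES if r != a
)


class EffectClass(str, Enum):
    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    NONSENSE = "nonsense"
    STOP_LOSS = "stop_loss"
    NONCODING = "noncoding"

    @property
    def changes_protein(self) -> bool:
        return self in (
            EffectClass.NONSYNONYMOUS,
            EffectClass.NONSENSE,
            EffectClass.STOP_LOSS,
        )


class GeneticCode:
    """Codon -> amino-acid map; stops are ``*``. Built from an NCBI table id."""

    def __init__(self, codon_map: Mapping[str, str]):
        if len(codon_map) != 64:
            raise ValueError("genetic code must define all 64 codons")
        self._map = {k.upper(): v for k, v in codon_map.items()}

    @classmethod
    def from_ncbi_id(cls, table_id: int = 1) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        codon_map = dict(table.forward_table)
        for stop in table.stop_codons:
            codon_map[stop] = "*"
        return cls(codon_map)

    def translate_codon(self, codon: str) -> str:
        return self._map[codon.upper()]

    def is_stop(self, codon: str) -> bool:
        return self.translate_codon(codon) == "*"


STANDARD_CODE = GeneticCode.from_ncbi_id(1)


@dataclass
class SiteCounts:
    """Expected synonymous / nonsynonymous site counts (fractional)."""

    syn_sites: float
    nonsyn_sites: float

    def __add__(self, other: "SiteCounts") -> "SiteCounts":
        return SiteCounts(
            self.syn_sites + other.syn_sites,
            self.nonsyn_sites + other.nonsyn_sites,
        )

    @property
    def total(self) -> float:
        return self.syn_sites + self.nonsyn_sites


@dataclass(frozen=True)
class SubstitutionModel:
    """Relative weights for the 12 substitution types (defaults uniform)."""

    weights: Mapping[tuple[str, str], float] = None

    def weight(self, ref: str, alt: str) -> float:
        if self.weights is None:
            return 1.0
        return float(self.weights[(ref, alt)])

    @classmethod
    def uniform(cls) -> "SubstitutionModel":
        return cls(None)

    @classmethod
    def kappa(cls, kappa: float) -> "SubstitutionModel":
        """Transition/transversion rate ratio model (kappa for transitions)."""
        w = {
            (r, a): (kappa if (r, a) in TRANSITIONS else 1.0)
            for (r, a) in SUBSTITUTIONS
        }
        return cls(w)


def _cds_index(gene: GeneAnnotation, position: int) -> int:
    if gene.strand == "+":
        return position - gene.start
    return gene.end - position


def classify_snp(
    gene: GeneAnnotation,
    position: int,
    ref: str,
    alt: str,
    code: GeneticCode = STANDARD_CODE,
) -> EffectClass:
    """Classify a genomic SNP within a coding gene.

    ``ref``/``alt`` are given on the genome's forward strand; for a minus
    strand gene they are complemented before the codon lookup. The reference
    allele must match the CDS at that position.
    """
    if not gene.is_coding or gene.cds_sequence is None:
        raise ValueError(f"gene {gene.gene_id}: no CDS sequence for classification")
    if not gene.contains(position):
        raise ValueError(
            f"position {position} outside gene {gene.gene_id} "
            f"({gene.start}-{gene.end})"
        )
    ref, alt = ref.upper(), alt.upper()
    if gene.strand == "-":
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    idx = _cds_index(gene, position)
    cds = gene.cds_sequence.upper()
    if cds[idx] != ref:
        raise ValueError(
            f"reference inconsistency at {gene.gene_id} CDS index {idx}: "
            f"CDS has {cds[idx]!r}, call has {ref!r}"
        )
    codon_start = (idx // 3) * 3
    if codon_start + 3 > len(cds):
        raise ValueError(f"partial codon at edge of gene {gene.gene_id}")
    codon = cds[codon_start : codon_start + 3]
    mutated = codon[: idx - codon_start] + alt + codon[idx - codon_start + 1 :]
    aa_ref = code.translate_codon(codon)
    aa_alt = code.translate_codon(mutated)
    if aa_ref == aa_alt:
        return EffectClass.SYNONYMOUS
    if aa_alt == "*":
        return EffectClass.NONSENSE
    if aa_ref == "*":
        return EffectClass.STOP_LOSS
    return EffectClass.NONSYNONYMOUS


def count_sites(cds: str, code: GeneticCode = STANDARD_CODE) -> SiteCounts:
    """Expected syn/nonsyn site counts for a CDS by per-codon enumeration.

    Each codon position contributes syn_share = (#synonymous of the 3
    possible substitutions)/3; totals over the CDS satisfy
    syn + nonsyn = len(cds). Internal stop codons are counted (with a
    warning); substitutions between stop codons count as synonymous.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    if any(b not in BASES for b in cds):
        raise ValueError("CDS contains non-ACGT characters")
    syn = 0.0
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if code.is_stop(codon) and i < n_codons - 1:
            warnings.warn(
                f"internal stop codon at codon {i}; counted anyway", stacklevel=2
            )
        aa = code.translate_codon(codon)
        for pos in range(3):
            for b in BASES:
                if b == codon[pos]:
                    continue
                mutated = codon[:pos] + b + codon[pos + 1 :]
                if code.translate_codon(mutated) == aa:
                    syn += 1.0 / 3.0
    return SiteCounts(syn_sites=syn, nonsyn_sites=len(cds) - syn)


def genome_site_counts(
    genes: Iterable[GeneAnnotation], code: GeneticCode = STANDARD_CODE
) -> SiteCounts:
    total = SiteCounts(0.0, 0.0)
    for g in genes:
        if g.is_coding and g.cds_sequence is not None:
            total = total + count_sites(g.cds_sequence, code)
    return total


def expected_nonsense_fraction(
    genes: Iterable[GeneAnnotation],
    code: GeneticCode = STANDARD_CODE,
    model: SubstitutionModel = SubstitutionModel.uniform(),
) -> float:
    """Fraction of weighted coding point mutations that create a stop codon.

    The numerator covers substitutions turning a non-stop codon into a stop;
    the denominator covers all possible coding substitutions.
    """
    num = 0.0
    den = 0.0
    for g in genes:
        if not g.is_coding or g.cds_sequence is None:
            continue
        cds = g.cds_sequence.upper()
        for i in range(0, len(cds), 3):
            codon = cds[i : i + 3]
            ref_is_stop = code.is_stop(codon)
            for pos in range(3):
                for b in BASES:
                    if b == codon[pos]:
                        continue
                    w = model.weight(codon[pos], b)
                    den += w
                    mutated = codon[:pos] + b + codon[pos + 1 :]
                    if not ref_is_stop and code.is_stop(mutated):
                        num += w
    if den == 0:
        return 0.0
    return num / den


def expected_tstv_neutral(
    model: SubstitutionModel = SubstitutionModel.uniform(),
) -> float:
    """Expected transition:transversion ratio under a substitution model.

    Uniform weights give 0.5 (each base has 1 transition and 2 transversion
    partners). Raises if the model allows no transversions.
    """
    ts = sum(model.weight(r, a) for (r, a) in SUBSTITUTIONS if (r, a) in TRANSITIONS)
    tv = sum(
        model.weight(r, a) for (r, a) in SUBSTITUTIONS if (r, a) not in TRANSITIONS
    )
    if tv == 0:
        raise ValueError("substitution model permits no transversions; ts:tv undefined")
    return ts / tv


def is_transition(ref: str, alt: str) -> bool:
    return (ref.upper(), alt.upper()) in TRANSITIONS
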