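"""Synthetic datasets with planted truth for every pipeline stage.

The generator emulates the lineage design of a two-treatment serial-transfer
evolution experiment: one organism, two pCO2-style treatments (labelled
"400" and "800"), six replicate lineages per treatment. It emits

* a reference genome of non-overlapping coding genes (lengths divisible by
  3, intergenic spacers wide enough that 50-bp promoter windows never
  overlap a neighbouring gene or window),
* per-lineage mutation tables with planted convergently selected genes,
  syn+nonsyn mutational hotspots, ancestral variants shared by every
  lineage, ancestrally heterozygous loci with partial fixation, and a
  Poisson-in-gene-length background,
* coverage tracks with per-lineage plasmid copy number, region-specific
  retention and planted chromosomal duplications,
* growth series whose underlying rate rises linearly with generation.

A master seed fans out to per-stage child seeds so stages can be
regenerated independently and the whole pipeline is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .codon import COMPLEMENT, EffectClass, STANDARD_CODE, classify_snp
from .curation import ReferenceVariantSet
from .model import (
    CoverageTrack,
    GeneAnnotation,
    GrowthSeries,
    LineageMeta,
    MutationRecord,
    MutationType,
)

BASES = np.array(["A", "C", "G", "T"])
STOPS = ("TAA", "TAG", "TGA")
CHROMOSOME = "chr"
PLASMID = "plasmid"


@dataclass
class PlasmidTruth:
    """Per-lineage plasmid state: overall copy number and region retention."""

    copy_number: float = 1.0
    retention: dict = field(
        default_factory=lambda: {"insertable": 1.0, "full_plasmid": 1.0, "reduced": 1.0}
    )


@dataclass
class SimulationDesign:
    """Study conditions for the generator (defaults mirror the lineage design)."""

    species: str = "phyto"
    partner: Optional[str] = None
    treatments: tuple = ("400", "800")
    replicates: int = 6
    n_genes: int = 2000
    gene_length_log_mean: float = math.log(800.0)
    gene_length_log_sd: float = 0.45
    gene_length_min: int = 150
    gene_length_max: int = 3999
    spacer_bp: int = 120
    mutations_per_lineage: float = 100.0
    intergenic_fraction: float = 0.1
    # planted convergence
    n_convergent: int = 5
    convergent_lineages: int = 4  # lineages per treatment receiving the gene
    convergent_extra: float = 0.5  # extra Poisson mutations per planted lineage
    # planted hotspots (syn+nonsyn elevated, not selection)
    n_hotspot: int = 3
    hotspot_lineages: int = 5
    # ancestral structure
    n_ancestral: int = 20
    n_ref_discrepancies: int = 10
    n_het_loci: int = 30
    het_fixation_prob: float = 0.30
    # de-novo frequency mixture: rare fraction ~ U(0.05, 0.5), rest fixed
    rare_fraction: float = 0.70
    # coverage truth
    chromosome_depth: float = 100.0
    plasmid_length: int = 200_000
    plasmid_truth: dict = field(default_factory=dict)  # lineage_id -> PlasmidTruth
    duplications: tuple = ()  # (start, end, fold) on the chromosome
    # growth truth
    ancestral_rate: float = 0.2  # per day
    rate_slope: float = 2e-4  # per generation
    rate_noise_sd: float = 0.05
    dilution: float = 26.0
    n_transfers: int = 20
    sampling_interval_h: float = 48.0
    cutoff_density: float = 1e6
    master_seed: int = 0

    def lineage_ids(self) -> list[str]:
        return [
            f"{self.species}_{t}_r{r + 1}"
            for t in self.treatments
            for r in range(self.replicates)
        ]

    def lineage_meta(self) -> list[LineageMeta]:
        return [
            LineageMeta(
                lineage_id=f"{self.species}_{t}_r{r + 1}",
                species=self.species,
                treatment=t,
                replicate=r + 1,
                partner=self.partner,
            )
            for t in self.treatments
            for r in range(self.replicates)
        ]

    def treatment_of(self, lineage_id: str) -> str:
        return lineage_id.rsplit("_", 2)[1]

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage generator fanned out from the master seed."""
        stage_offset = sum(ord(c) for c in stage)
        ss = np.random.SeedSequence([self.master_seed, stage_offset])
        return np.random.default_rng(ss)


@dataclass
class Reference:
    genes: list[GeneAnnotation]
    genome: dict  # element_id -> sequence string
    element_lengths: dict

    def gene_by_id(self, gene_id: str) -> GeneAnnotation:
        return self._index[gene_id]

    def __post_init__(self) -> None:
        self._index = {g.gene_id: g for g in self.genes}

    @property
    def coding_size(self) -> int:
        return sum(g.length for g in self.genes)


@dataclass
class TruthLabels:
    gene_labels: dict  # gene_id -> "neutral" | "convergent:<treatment>" | "hotspot"
    variant_labels: dict  # (element, position, alt, lineage) -> kind
    reference_variants: ReferenceVariantSet
    plasmid_truth: dict  # lineage_id -> PlasmidTruth
    growth_truth: dict  # lineage_id -> {"ancestral_rate", "rate_slope"}

    def genes_with_label(self, prefix: str) -> list[str]:
        return [g for g, lab in self.gene_labels.items() if lab.startswith(prefix)]


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------

_STOP_CODES = frozenset(
    16 * "ACGT".index(c[0]) + 4 * "ACGT".index(c[1]) + "ACGT".index(c[2])
    for c in STOPS
)


def _random_cds(length: int, rng: np.random.Generator) -> str:
    """ATG + random internal non-stop codons + a stop codon."""
    n_codons = length // 3
    if n_codons < 3:
        raise ValueError("CDS needs at least 3 codons")
    body = rng.integers(0, 4, size=(n_codons - 2, 3))
    codes = body[:, 0] * 16 + body[:, 1] * 4 + body[:, 2]
    bad = np.isin(codes, list(_STOP_CODES))
    while bad.any():
        body[bad] = rng.integers(0, 4, size=(int(bad.sum()), 3))
        codes = body[:, 0] * 16 + body[:, 1] * 4 + body[:, 2]
        bad = np.isin(codes, list(_STOP_CODES))
    middle = "".join(BASES[body.ravel()]) if body.size else ""
    return "ATG" + middle + STOPS[rng.integers(len(STOPS))]


def _revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def generate_reference(design: SimulationDesign, rng=None) -> Reference:
    """Non-overlapping genes on one chromosome, alternating strands."""
    if design.n_genes < 1:
        raise ValueError("need at least one gene")
    if rng is None:
        rng = design.stage_rng("reference")
    raw = rng.lognormal(design.gene_length_log_mean, design.gene_length_log_sd,
                        size=design.n_genes)
    lengths = np.clip(raw, design.gene_length_min, design.gene_length_max).astype(int)
    lengths = (lengths // 3) * 3
    genes: list[GeneAnnotation] = []
    chunks: list[str] = []
    pos = 1
    for i, length in enumerate(lengths):
        spacer = "".join(rng.choice(BASES, size=design.spacer_bp))
        chunks.append(spacer)
        pos += design.spacer_bp
        strand = "+" if i % 2 == 0 else "-"
        cds = _random_cds(int(length), rng)
        genes.append(
            GeneAnnotation(
                gene_id=f"g{i + 1:05d}",
                element_id=CHROMOSOME,
                start=pos,
                end=pos + int(length) - 1,
                strand=strand,
                is_coding=True,
                cds_sequence=cds,
            )
        )
        chunks.append(cds if strand == "+" else _revcomp(cds))
        pos += int(length)
    chunks.append("".join(rng.choice(BASES, size=design.spacer_bp)))
    genome = "".join(chunks)
    return Reference(
        genes=genes,
        genome={CHROMOSOME: genome},
        element_lengths={CHROMOSOME: len(genome), PLASMID: design.plasmid_length},
    )


# ---------------------------------------------------------------------------
# Mutation tables
# ---------------------------------------------------------------------------

def _random_alt(ref: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != ref]
    return choices[rng.integers(3)]


def _denovo_frequency(design: SimulationDesign, rng: np.random.Generator) -> float:
    if rng.random() < design.rare_fraction:
        return float(rng.uniform(0.05, 0.5))
    return 1.0


def _planted_snp(
    gene: GeneAnnotation,
    want: EffectClass,
    rng: np.random.Generator,
    genome: str,
    max_tries: int = 200,
) -> tuple[int, str, str]:
    """Rejection-sample a genomic SNP in ``gene`` with the wanted effect."""
    for _ in range(max_tries):
        position = int(rng.integers(gene.start, gene.end + 1))
        ref = genome[position - 1]
        alt = _random_alt(ref, rng)
        if classify_snp(gene, position, ref, alt) is want:
            return position, ref, alt
    raise RuntimeError(
        f"could not plant a {want.value} SNP in gene {gene.gene_id}"
    )


def simulate_mutations(
    design: SimulationDesign, reference: Reference, rng=None
) -> tuple[list[MutationRecord], TruthLabels]:
    """Per-lineage mutation records plus the planted-truth labels."""
    if rng is None:
        rng = design.stage_rng("mutations")
    genome = reference.genome[CHROMOSOME]
    genome_len = len(genome)
    lineages = design.lineage_ids()
    genes = reference.genes
    lengths = np.array([g.length for g in genes], dtype=float)
    gene_probs = lengths / lengths.sum()
    gene_starts = np.array([g.start for g in genes])
    gene_ends = np.array([g.end for g in genes])

    gene_labels = {g.gene_id: "neutral" for g in genes}
    variant_labels: dict = {}
    records: list[MutationRecord] = []

    def emit(lineage, element, position, ref, alt, mtype, freq, label):
        records.append(
            MutationRecord(
                lineage_id=lineage,
                element_id=element,
                position=position,
                ref_allele=ref,
                alt_allele=alt,
                mut_type=mtype,
                frequency=freq,
            )
        )
        variant_labels[(element, position, alt, lineage)] = label

    # --- background de-novo mutations, Poisson in gene length -------------
    for lineage in lineages:
        n_total = rng.poisson(design.mutations_per_lineage)
        n_intergenic = rng.binomial(n_total, design.intergenic_fraction)
        n_genic = n_total - n_intergenic
        gene_hits = rng.multinomial(n_genic, gene_probs)
        for gi in np.flatnonzero(gene_hits):
            g = genes[gi]
            for _ in range(int(gene_hits[gi])):
                position = int(rng.integers(g.start, g.end + 1))
                ref = genome[position - 1]
                alt = _random_alt(ref, rng)
                emit(
                    lineage, CHROMOSOME, position, ref, alt,
                    MutationType.SNP, _denovo_frequency(design, rng), "de_novo",
                )
        for _ in range(int(n_intergenic)):
            # rejection-sample an intergenic position
            while True:
                position = int(rng.integers(1, genome_len + 1))
                i = int(np.searchsorted(gene_starts, position, side="right")) - 1
                if i < 0 or position > gene_ends[i]:
                    break
            ref = genome[position - 1]
            alt = _random_alt(ref, rng)
            emit(
                lineage, CHROMOSOME, position, ref, alt,
                MutationType.SNP, _denovo_frequency(design, rng), "de_novo",
            )

    # --- planted convergent genes -----------------------------------------
    candidate_ids = rng.permutation(len(genes))
    cursor = 0
    for k in range(design.n_convergent):
        g = genes[candidate_ids[cursor]]
        cursor += 1
        treatment = design.treatments[k % len(design.treatments)]
        gene_labels[g.gene_id] = f"convergent:{treatment}"
        group = [l for l in lineages if design.treatment_of(l) == treatment]
        chosen = rng.choice(group, size=design.convergent_lineages, replace=False)
        for lineage in chosen:
            n_mut = 1 + rng.poisson(design.convergent_extra)
            for _ in range(n_mut):
                position, ref, alt = _planted_snp(
                    g, EffectClass.NONSYNONYMOUS, rng, genome
                )
                emit(
                    lineage, CHROMOSOME, position, ref, alt,
                    MutationType.SNP, 1.0, "planted_convergent",
                )

    # --- planted hotspots (both treatments, syn and nonsyn alike) ---------
    for _ in range(design.n_hotspot):
        g = genes[candidate_ids[cursor]]
        cursor += 1
        gene_labels[g.gene_id] = "hotspot"
        for treatment in design.treatments:
            group = [l for l in lineages if design.treatment_of(l) == treatment]
            chosen = rng.choice(group, size=design.hotspot_lineages, replace=False)
            for lineage in chosen:
                for want in (EffectClass.SYNONYMOUS, EffectClass.NONSYNONYMOUS):
                    for _ in range(1 + rng.poisson(0.5)):
                        position, ref, alt = _planted_snp(g, want, rng, genome)
                        emit(
                            lineage, CHROMOSOME, position, ref, alt,
                            MutationType.SNP, 1.0, "hotspot",
                        )

    # --- ancestral variants (in every lineage at 100%) --------------------
    anc_positions = rng.choice(genome_len, size=design.n_ancestral, replace=False) + 1
    for position in anc_positions:
        ref = genome[position - 1]
        alt = _random_alt(ref, rng)
        for lineage in lineages:
            emit(
                lineage, CHROMOSOME, int(position), ref, alt,
                MutationType.SNP, 1.0, "ancestral",
            )

    # --- reference discrepancies (100% in ancestral re-assembly) ----------
    used = set(int(p) for p in anc_positions)
    disc = []
    while len(disc) < design.n_ref_discrepancies:
        position = int(rng.integers(1, genome_len + 1))
        if position in used:
            continue
        used.add(position)
        ref = genome[position - 1]
        alt = _random_alt(ref, rng)
        disc.append((CHROMOSOME, position, alt))
        for lineage in lineages:
            emit(
                lineage, CHROMOSOME, position, ref, alt,
                MutationType.SNP, 1.0, "reference_discrepancy",
            )

    # --- ancestrally heterozygous loci with partial fixation --------------
    het_loci = []
    for _ in range(design.n_het_loci):
        position = int(rng.integers(1, genome_len + 1))
        if position in used:
            continue
        used.add(position)
        het_loci.append((CHROMOSOME, position))
        ref = genome[position - 1]
        alt = _random_alt(ref, rng)
        for lineage in lineages:
            if rng.random() < design.het_fixation_prob:
                emit(
                    lineage, CHROMOSOME, position, ref, alt,
                    MutationType.SNP, 1.0, "het_fixed",
                )
            else:
                freq = float(np.clip(rng.normal(0.5, 0.05), 0.3, 0.7))
                emit(
                    lineage, CHROMOSOME, position, ref, alt,
                    MutationType.SNP, freq, "het_nonfixed",
                )

    ref_set = ReferenceVariantSet(
        fixed_discrepancies=frozenset(disc),
        heterozygous_loci=frozenset(het_loci),
    )
    truth = TruthLabels(
        gene_labels=gene_labels,
        variant_labels=variant_labels,
        reference_variants=ref_set,
        plasmid_truth=dict(design.plasmid_truth),
        growth_truth={
            l: {"ancestral_rate": design.ancestral_rate, "rate_slope": design.rate_slope}
            for l in lineages
        },
    )
    return records, truth


# ---------------------------------------------------------------------------
# Coverage tracks
# ---------------------------------------------------------------------------

REGION_INTERVALS = {
    "insertable": (170_000, 180_000),
    "full_plasmid": (120_000, 130_000),
    "reduced": (40_000, 50_000),
}


def simulate_coverage(
    design: SimulationDesign,
    reference: Reference,
    rng=None,
    lineages: Optional[Sequence[str]] = None,
) -> dict[tuple[str, str], CoverageTrack]:
    """Poisson-sampled depth tracks for chromosome and plasmid per lineage.

    The plasmid's expected depth is chromosome depth x copy number, scaled
    within each named region by that region's retention; positions outside
    the named windows follow the full-plasmid retention. Planted chromosome
    duplications multiply the local expectation by their fold.
    """
    if rng is None:
        rng = design.stage_rng("coverage")
    if lineages is None:
        lineages = design.lineage_ids()
    chrom_len = reference.element_lengths[CHROMOSOME]
    tracks: dict[tuple[str, str], CoverageTrack] = {}
    for lineage in lineages:
        lam = np.full(chrom_len, design.chromosome_depth)
        for start, end, fold in design.duplications:
            lam[start - 1 : end] *= fold
        depth = rng.poisson(lam).astype(float)
        tracks[(lineage, CHROMOSOME)] = CoverageTrack(lineage, CHROMOSOME, depth)

        truth = design.plasmid_truth.get(lineage, PlasmidTruth())
        base = design.chromosome_depth * truth.copy_number
        lam_p = np.full(
            design.plasmid_length, base * truth.retention.get("full_plasmid", 1.0)
        )
        for name, (start, end) in REGION_INTERVALS.items():
            lam_p[start - 1 : end] = base * truth.retention.get(name, 1.0)
        depth_p = rng.poisson(lam_p).astype(float)
        tracks[(lineage, PLASMID)] = CoverageTrack(lineage, PLASMID, depth_p)
    return tracks


# ---------------------------------------------------------------------------
# Growth series
# ---------------------------------------------------------------------------

def simulate_growth(
    design: SimulationDesign, rng=None, lineages: Optional[Sequence[str]] = None
) -> dict[str, GrowthSeries]:
    """Serial-transfer density series with linearly evolving growth rate.

    Within transfer k the rate is ancestral + slope x generation_k + noise;
    densities are sampled every ``sampling_interval_h`` and the culture is
    diluted when a reading crosses the cutoff density.
    """
    if rng is None:
        rng = design.stage_rng("growth")
    if lineages is None:
        lineages = design.lineage_ids()
    gens = math.log2(design.dilution)
    out = {}
    for lineage in lineages:
        times, dens, transfer_times = [], [], []
        t = 0.0
        n = design.cutoff_density / design.dilution
        for k in range(design.n_transfers):
            # dilution happens at the crossing reading; nudge the event just
            # past it so the crossing observation stays in the prior window
            transfer_times.append(t + 1e-9 if k else -1e-9)
            rate = (
                design.ancestral_rate
                + design.rate_slope * k * gens
                + (rng.normal(0.0, design.rate_noise_sd) if design.rate_noise_sd else 0.0)
            )
            rate = max(rate, 1e-3)
            n0, t0 = n, t
            while True:
                t += design.sampling_interval_h
                n = n0 * math.exp(rate * (t - t0) / 24.0)
                times.append(t)
                dens.append(n)
                if n >= design.cutoff_density:
                    break
            n = n / design.dilution
        out[lineage] = GrowthSeries(
            lineage_id=lineage,
            times_h=np.array(times),
            densities=np.array(dens),
            transfer_times_h=np.array(transfer_times),
            dilution_factor=design.dilution,
        )
    return out


def simulate_exponential_assay(
    rate_per_day: float,
    n_points: int = 9,
    dt_h: float = 6.0,
    noise_sd: float = 0.0,
    rng=None,
    n0: float = 1e4,
    lineage_id: str = "assay",
    dilution_factor: float = 26.0,
) -> GrowthSeries:
    """A single-window exponential growth assay for EGR estimation.

    Multiplicative lognormal observation noise with the given log-SD.
    """
    if rng is None:
        rng = np.random.default_rng()
    times = dt_h * np.arange(1, n_points + 1)
    dens = n0 * np.exp(rate_per_day * times / 24.0)
    if noise_sd:
        dens = dens * rng.lognormal(0.0, noise_sd, size=n_points)
    return GrowthSeries(
        lineage_id=lineage_id,
        times_h=times,
        densities=dens,
        transfer_times_h=np.array([0.0]),
        dilution_factor=dilution_factor,
    )


# ---------------------------------------------------------------------------
# Dataset emission
# ---------------------------------------------------------------------------

def generate_dataset(design: SimulationDesign, outdir: Optional[str] = None):
    """Generate all stages; optionally write the directory layout.

    Returns (reference, mutations, truth, coverage tracks, growth series).
    """
    reference = generate_reference(design)
    mutations, truth = simulate_mutations(design, reference)
    coverage = simulate_coverage(design, reference)
    growth = simulate_growth(design)
    if outdir is not None:
        import os

        from . import io as evio

        os.makedirs(outdir, exist_ok=True)
        os.makedirs(os.path.join(outdir, "coverage"), exist_ok=True)
        os.makedirs(os.path.join(outdir, "truth"), exist_ok=True)
        evio.write_annotation(reference.genes, os.path.join(outdir, "annotation.gff3"))
        evio.write_cds_fasta(
            {g.gene_id: g.cds_sequence for g in reference.genes},
            os.path.join(outdir, "cds.fasta"),
        )
        evio.write_mutations(mutations, os.path.join(outdir, "mutations.tsv"))
        evio.write_lineage_meta(design.lineage_meta(), os.path.join(outdir, "lineages.tsv"))
        for (lineage, element), track in coverage.items():
            evio.write_coverage(
                track,
                os.path.join(outdir, "coverage", f"{lineage}_{element}.bedgraph"),
            )
        evio.write_growth(list(growth.values()), os.path.join(outdir, "growth.csv"))
        pd.DataFrame(
            [(g, lab) for g, lab in truth.gene_labels.items()],
            columns=["gene_id", "label"],
        ).to_csv(os.path.join(outdir, "truth", "gene_labels.tsv"), sep="\t", index=False)
        pd.DataFrame(
            [
                (e, p, a, l, lab)
                for (e, p, a, l), lab in truth.variant_labels.items()
            ],
            columns=["element", "position", "alt", "lineage", "label"],
        ).to_csv(
            os.path.join(outdir, "truth", "variant_labels.tsv"), sep="\t", index=False
        )
    return reference, mutations, truth, coverage, growth
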