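"""Readers and writers for the file dialects the pipeline consumes.

Formats: GFF3 subset (gene features), FASTA (CDS sequences), a documented
mutation TSV dialect, bedGraph coverage, lineage-metadata TSV and growth CSV.
All readers validate on the way in and convert to the internal 1-based
inclusive coordinate convention.
"""

from __future__ import annotations

import os
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    CoverageTrack,
    GeneAnnotation,
    GrowthSeries,
    LineageMeta,
    MutationRecord,
    MutationType,
)

MUTATION_COLUMNS = ("lineage", "element", "position", "ref", "alt", "type", "frequency")


class ParseError(ValueError):
    pass


class SchemaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# GFF3 subset (gene features only)
# ---------------------------------------------------------------------------

def _gff_attributes(attr: str) -> dict:
    out = {}
    for chunk in attr.strip().split(";"):
        if not chunk:
            continue
        if "=" not in chunk:
            raise ParseError(f"malformed attribute chunk {chunk!r}")
        k, v = chunk.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_annotation(path: str) -> list[GeneAnnotation]:
    """Read gene features from a GFF3-subset file."""
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            seqid, _source, ftype, start, end, _score, strand, _phase, attr = fields
            if ftype != "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            attrs = _gff_attributes(attr)
            gene_id = attrs.get("ID")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: gene feature lacks ID attribute")
            if gene_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene ID {gene_id!r}")
            seen.add(gene_id)
            is_coding = attrs.get("coding", "true").lower() != "false"
            try:
                genes.append(
                    GeneAnnotation(
                        gene_id=gene_id,
                        element_id=seqid,
                        start=start_i,
                        end=end_i,
                        strand=strand,
                        is_coding=is_coding,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_annotation(genes: Sequence[GeneAnnotation], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if not g.is_coding:
                attrs += ";coding=false"
            fh.write(
                f"{g.element_id}\tevoconverge\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def read_cds_fasta(path: str) -> dict[str, str]:
    """Map gene_id -> CDS sequence from a FASTA file."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_cds_fasta(cds: dict[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene_id, description="") for gene_id, seq in cds.items()
    ]
    SeqIO.write(records, path, "fasta")


def attach_cds(
    genes: Sequence[GeneAnnotation], cds: dict[str, str]
) -> list[GeneAnnotation]:
    """Return annotations with CDS sequences attached where available."""
    out = []
    for g in genes:
        seq = cds.get(g.gene_id)
        if seq is None:
            out.append(g)
        else:
            out.append(
                GeneAnnotation(
                    g.gene_id, g.element_id, g.start, g.end, g.strand,
                    g.is_coding, seq,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Mutation TSV dialect
# ---------------------------------------------------------------------------

def read_mutations(path: str) -> list[MutationRecord]:
    """Read the long-format mutation table (one row per call per lineage)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    extra_cols = [c for c in df.columns if c not in MUTATION_COLUMNS]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        freq = float(d["frequency"])
        rec = MutationRecord(
            lineage_id=d["lineage"],
            element_id=d["element"],
            position=int(d["position"]),
            ref_allele=d["ref"],
            alt_allele=d["alt"],
            mut_type=MutationType(d["type"]),
            frequency=freq,
            extra={c: d[c] for c in extra_cols},
        )
        records.append(rec)
    return records


def write_mutations(records: Sequence[MutationRecord], path: str) -> None:
    extra_cols = sorted({k for r in records for k in r.extra})
    rows = []
    for r in records:
        row = {
            "lineage": r.lineage_id,
            "element": r.element_id,
            "position": r.position,
            "ref": r.ref_allele,
            "alt": r.alt_allele,
            "type": r.mut_type.value,
            "frequency": r.frequency,
        }
        for c in extra_cols:
            row[c] = r.extra.get(c, "")
        rows.append(row)
    pd.DataFrame(rows, columns=list(MUTATION_COLUMNS) + extra_cols).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# bedGraph coverage
# ---------------------------------------------------------------------------

def read_coverage(
    path: str,
    lineage_id: str = "",
    element_length: Optional[int] = None,
) -> CoverageTrack:
    """Read a single-replicon bedGraph into a CoverageTrack.

    bedGraph intervals are 0-based half-open; the track is 1-based inclusive.
    Gaps are filled with depth 0. If ``element_length`` is given, intervals
    beyond it are rejected; otherwise the track ends at the last interval.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["element", "start", "end", "depth"],
    )
    if df.empty:
        raise ParseError(f"{path}: empty bedGraph")
    elements = df["element"].unique()
    if len(elements) != 1:
        raise ParseError(f"{path}: expected one replicon, found {list(elements)}")
    df = df.sort_values(["start", "end"]).reset_index(drop=True)
    if (df["end"] <= df["start"]).any():
        raise ParseError(f"{path}: empty or inverted interval")
    overlaps = df["start"].to_numpy()[1:] < df["end"].to_numpy()[:-1]
    if overlaps.any():
        raise ParseError(f"{path}: overlapping intervals")
    last = int(df["end"].max())
    length = element_length if element_length is not None else last
    if last > length:
        raise ParseError(
            f"{path}: interval extends to {last}, beyond replicon length {length}"
        )
    depth = np.zeros(length, dtype=float)
    for start, end, d in zip(df["start"], df["end"], df["depth"]):
        depth[int(start) : int(end)] = float(d)
    return CoverageTrack(lineage_id=lineage_id, element_id=str(elements[0]), depth=depth)


def write_coverage(track: CoverageTrack, path: str) -> None:
    """Write a CoverageTrack as run-length-encoded bedGraph (0-based half-open)."""
    depth = track.depth
    with open(path, "w") as fh:
        if depth.size == 0:
            return
        change = np.flatnonzero(np.diff(depth)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [depth.size]])
        for s, e in zip(starts, ends):
            d = depth[s]
            fh.write(f"{track.element_id}\t{s}\t{e}\t{d:g}\n")


# ---------------------------------------------------------------------------
# Lineage metadata and growth series
# ---------------------------------------------------------------------------

def read_lineage_meta(path: str) -> list[LineageMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"lineage", "species", "treatment", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    metas = []
    seen = set()
    for row in df.itertuples(index=False):
        key = (row.species, row.treatment, int(row.replicate))
        if key in seen:
            raise SchemaError(f"{path}: duplicate (species, treatment, replicate) {key}")
        seen.add(key)
        metas.append(
            LineageMeta(
                lineage_id=row.lineage,
                species=row.species,
                treatment=row.treatment,
                replicate=int(row.replicate),
                partner=getattr(row, "partner", None),
            )
        )
    return metas


def write_lineage_meta(metas: Sequence[LineageMeta], path: str) -> None:
    pd.DataFrame(
        [
            {
                "lineage": m.lineage_id,
                "species": m.species,
                "treatment": m.treatment,
                "replicate": m.replicate,
                "partner": m.partner or "",
            }
            for m in metas
        ]
    ).to_csv(path, sep="\t", index=False)


def read_growth(path: str, dilution_factor: float) -> dict[str, GrowthSeries]:
    """Read growth CSV (lineage_id, time_h, density_cells_per_ml, transfer_id).

    A new ``transfer_id`` value marks the observation block following a
    transfer; transfer times are taken as the time of each block's first
    observation minus the sampling offset (the block start).
    """
    df = pd.read_csv(path)
    required = {"lineage_id", "time_h", "density_cells_per_ml", "transfer_id"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    out = {}
    for lineage_id, sub in df.groupby("lineage_id", sort=False):
        sub = sub.sort_values("time_h")
        times = sub["time_h"].to_numpy(float)
        block_first = sub.groupby("transfer_id", sort=False)["time_h"].min().to_numpy()
        # the dilution happens one sampling interval before the block's first
        # reading (at the previous block's crossing reading)
        delta = float(np.median(np.diff(times))) if times.size > 1 else 0.0
        out[str(lineage_id)] = GrowthSeries(
            lineage_id=str(lineage_id),
            times_h=times,
            densities=sub["density_cells_per_ml"].to_numpy(float),
            transfer_times_h=block_first - delta + 1e-9,
            dilution_factor=dilution_factor,
        )
    return out


def write_growth(series: Sequence[GrowthSeries], path: str) -> None:
    rows = []
    for s in series:
        # assign each observation to its transfer block
        idx = np.searchsorted(s.transfer_times_h, s.times_h, side="left") - 1
        idx = np.clip(idx, 0, max(s.n_transfers - 1, 0))
        for t, n, k in zip(s.times_h, s.densities, idx):
            rows.append(
                {
                    "lineage_id": s.lineage_id,
                    "time_h": t,
                    "density_cells_per_ml": n,
                    "transfer_id": int(k),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Dataset-level referential integrity
# ---------------------------------------------------------------------------

def validate_dataset(directory: str) -> list[str]:
    """Cross-file referential checks on a dataset directory.

    Expects ``annotation.gff3``, ``mutations.tsv`` and ``lineages.tsv``;
    returns a list of human-readable problems (empty when consistent).
    """
    problems: list[str] = []
    ann_path = os.path.join(directory, "annotation.gff3")
    mut_path = os.path.join(directory, "mutations.tsv")
    meta_path = os.path.join(directory, "lineages.tsv")
    for p in (ann_path, mut_path, meta_path):
        if not os.path.exists(p):
            problems.append(f"missing file: {os.path.basename(p)}")
    if problems:
        return problems
    genes = read_annotation(ann_path)
    mutations = read_mutations(mut_path)
    metas = read_lineage_meta(meta_path)
    elements = {g.element_id for g in genes}
    lineages = {m.lineage_id for m in metas}
    for rec in mutations:
        if rec.element_id not in elements:
            problems.append(
                f"mutation at {rec.element_id}:{rec.position} references "
                f"unknown element {rec.element_id!r}"
            )
        if rec.lineage_id not in lineages:
            problems.append(
                f"mutation at {rec.element_id}:{rec.position} references "
                f"lineage {rec.lineage_id!r} with no metadata"
            )
    return problems
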