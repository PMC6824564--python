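"""Readers/writers for GenBank, FASTA and aligned FASTA, plus region
classification of genome coordinates (CDS / intron / IGS).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .records import GENIC_KINDS, Feature, PlastomeRecord, RegionLabel

_FEATURE_KINDS = {"gene": "gene", "CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------- GenBank

def read_genbank(path: str | os.PathLike) -> PlastomeRecord:
    """Read one annotated plastome from a GenBank flat file.

    Gene/CDS/tRNA/rRNA features are captured with their exon intervals;
    introns are implied by gaps between exons and derived on demand by
    :func:`classify_region`. Raises :class:`ParseError` on a missing
    sequence block or a feature running past the sequence end.
    """
    try:
        rec = SeqIO.read(path, "genbank")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    seq = str(rec.seq).upper()
    if not seq:
        raise ParseError(f"{path}: GenBank record has no ORIGIN sequence")
    n = len(seq)
    feats: list[Feature] = []
    for f in rec.features:
        kind = _FEATURE_KINDS.get(f.type)
        if kind is None:
            continue
        name = (f.qualifiers.get("gene") or f.qualifiers.get("locus_tag")
                or [f.type])[0]
        intervals = sorted((int(p.start), int(p.end)) for p in f.location.parts)
        for s, e in intervals:
            if e > n:
                raise ParseError(
                    f"{path}: feature {name!r} ({f.type}) interval ({s}, {e}) "
                    f"extends beyond sequence length {n}")
        pseudo = "pseudo" in f.qualifiers or "pseudogene" in f.qualifiers
        strand = "-" if f.location.strand == -1 else "+"
        feats.append(Feature(kind=kind, name=name, intervals=intervals,
                             strand=strand, pseudo=pseudo))
    circular = rec.annotations.get("topology", "circular") == "circular"
    return PlastomeRecord(taxon_label=rec.id or rec.name, sequence=seq,
                          is_circular=circular, features=feats)


def write_genbank(record: PlastomeRecord, path: str | os.PathLike) -> None:
    rec = SeqRecord(Seq(record.sequence), id=record.taxon_label[:16] or "rec",
                    name=record.taxon_label[:16] or "rec",
                    description=record.taxon_label)
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if record.is_circular else "linear"
    for f in record.features:
        strand = -1 if f.strand == "-" else 1
        parts = [FeatureLocation(s, e, strand=strand) for s, e in f.intervals]
        loc = parts[0] if len(parts) == 1 else CompoundLocation(parts)
        quals = {"gene": [f.name]}
        if f.pseudo:
            quals["pseudo"] = [""]
        ftype = "gene" if f.kind in ("gene", "pseudogene") else f.kind
        rec.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    SeqIO.write(rec, path, "genbank")


# ------------------------------------------------------------------ FASTA

def read_fasta_many(path: str | os.PathLike) -> list[PlastomeRecord]:
    """Read unaligned FASTA: one plastome per record, no annotation.

    Labels are the header up to the first whitespace. Gap characters are
    an error here (aligned input goes through :func:`read_alignment`).
    """
    records: list[PlastomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        label = rec.id
        if label in seen:
            raise ParseError(f"{path}: duplicate label {label!r}")
        seen.add(label)
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: empty sequence for {label!r}")
        if "-" in seq:
            raise ParseError(
                f"{path}: gap characters in {label!r}; this reader takes "
                "unaligned FASTA (use read_alignment for aligned input)")
        records.append(PlastomeRecord(taxon_label=label, sequence=seq))
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[PlastomeRecord], path: str | os.PathLike,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.taxon_label}\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i:i + width] + "\n")


# -------------------------------------------------------------- Alignment

@dataclass
class Alignment:
    """A multiple sequence alignment over {A,C,G,T,N,-}.

    Keeps per-row maps between alignment columns and ungapped genome
    coordinates, which the SI caller and SSR matcher use to establish
    homology across taxa.
    """

    labels: list[str]
    rows: list[str]
    _col2seq: list[np.ndarray] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ParseError("ragged alignment rows")
        self.rows = [r.upper() for r in self.rows]
        if not self._col2seq:
            for r in self.rows:
                arr = np.full(len(r), -1, dtype=np.int64)
                pos = 0
                for i, c in enumerate(r):
                    if c != "-":
                        arr[i] = pos
                        pos += 1
                self._col2seq.append(arr)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, row: int) -> str:
        return self.rows[row].replace("-", "")

    def col_to_seq(self, row: int, col: int) -> int:
        """Ungapped coordinate at an alignment column; -1 at a gap."""
        return int(self._col2seq[row][col])

    def seq_to_col(self, row: int, pos: int) -> int:
        hits = np.nonzero(self._col2seq[row] == pos)[0]
        if len(hits) == 0:
            raise IndexError(f"row {row}: ungapped position {pos} not present")
        return int(hits[0])

    def columns_for(self, row: int, start: int, end: int) -> np.ndarray:
        """Alignment columns carrying ungapped positions [start, end)."""
        mask = (self._col2seq[row] >= start) & (self._col2seq[row] < end)
        return np.nonzero(mask)[0]

    def to_array(self) -> np.ndarray:
        return np.frombuffer("".join(self.rows).encode(),
                             dtype="S1").reshape(self.n_rows, self.n_cols)


def read_alignment(path: str | os.PathLike) -> Alignment:
    """Read an aligned FASTA (all rows equal length)."""
    try:
        aln = AlignIO.read(path, "fasta")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return Alignment(labels=[r.id for r in aln],
                     rows=[str(r.seq) for r in aln])


def write_alignment(aln: Alignment, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for label, row in zip(aln.labels, aln.rows):
            fh.write(f">{label}\n{row}\n")


# ---------------------------------------------------- region classification

def classify_region(record: PlastomeRecord, position: int) -> RegionLabel:
    """Assign a genome coordinate to CDS, intron, or IGS.

    tRNA/rRNA and pseudogene bodies count as genic (CDS-class): the
    three-way split treats every annotated gene body as non-spacer. The
    compartment comes from the record's partition when present.
    """
    n = record.length_bp
    if not (0 <= position < n):
        raise IndexError(f"position {position} outside [0, {n})")
    compartment = (record.partition.compartment_of(position)
                   if record.partition else "unassigned")

    genic = [f for f in record.features if f.kind in GENIC_KINDS]
    # prefer the multi-exon variant of a gene annotated both as gene and CDS
    by_name: dict[str, Feature] = {}
    for f in genic:
        cur = by_name.get(f.name)
        if cur is None or len(f.intervals) > len(cur.intervals):
            by_name[f.name] = f
    feats = sorted(by_name.values(), key=lambda f: f.span)

    in_intron = False
    for f in feats:
        s, e = f.span
        if s <= position < e:
            if any(a <= position < b for a, b in f.intervals):
                return RegionLabel("CDS", compartment)
            in_intron = True
    if in_intron:
        return RegionLabel("intron", compartment)

    if not feats:
        raise ValueError("record has no genic features; cannot label IGS")
    # nearest gene upstream (ending at or before) and downstream, circularly
    prev_f = min(feats, key=lambda f: (position - f.span[1]) % n)
    next_f = min(feats, key=lambda f: (f.span[0] - position) % n)
    return RegionLabel("IGS", compartment,
                       flanking=f"{prev_f.name}-{next_f.name}")
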