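"""Perfect microsatellite (SSR) scanning with per-class copy thresholds.

A locus qualifies when a primitive 1-5 bp motif is tandemly repeated at
least 10 (mono), 5 (di), 4 (tri), 3 (tetra) or 2 (penta) times. Runs
containing N are broken; only whole motif copies count; each physical
repeat is reported once under its primitive motif.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from ._seq import revcomp
from .io import Alignment, classify_region
from .records import PlastomeRecord, QuadripartitePartition, RegionLabel

COPY_THRESHOLDS: dict[int, int] = {1: 10, 2: 5, 3: 4, 4: 3, 5: 2}


@dataclass
class SSRLocus:
    motif: str                 # canonical: lexicographically smallest rotation
    unit_len: int
    copies: int
    start: int
    end: int
    region: Optional[RegionLabel] = None
    ir_duplicate: bool = False

    @property
    def length_bp(self) -> int:
        return self.unit_len * self.copies


def canonical_motif(unit: str) -> str:
    """Lexicographically smallest rotation; strand is preserved (A-runs
    and T-runs remain distinct classes)."""
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def is_primitive(unit: str) -> bool:
    """True unless the unit is a whole-number repetition of a shorter one."""
    n = len(unit)
    for p in range(1, n):
        if n % p == 0 and unit == unit[:p] * (n // p):
            return False
    return True


def scan_ssrs(record: PlastomeRecord | str,
              thresholds: Optional[dict[int, int]] = None,
              annotate: bool = True) -> list[SSRLocus]:
    """All maximal perfect SSRs in the sequence meeting class thresholds.

    For each unit length the sequence is scanned for maximal runs with
    period `unit_len`; the locus spans the whole copies only, anchored at
    the leftmost phase. Non-primitive motifs are skipped, so a repeat is
    reported exactly once. Sorted by start.
    """
    thresholds = thresholds or COPY_THRESHOLDS
    if isinstance(record, str):
        seq, rec = record.upper(), None
    else:
        seq, rec = record.sequence, record
    n = len(seq)
    loci: list[SSRLocus] = []
    for unit_len, min_copies in sorted(thresholds.items()):
        i = 0
        while i + unit_len <= n:
            unit = seq[i:i + unit_len]
            if "N" in unit or not is_primitive(unit):
                i += 1
                continue
            j = i + unit_len
            while j < n and seq[j] == seq[j - unit_len] and seq[j] != "N":
                j += 1
            copies = (j - i) // unit_len
            if copies >= min_copies:
                end = i + copies * unit_len
                loci.append(SSRLocus(motif=canonical_motif(unit),
                                     unit_len=unit_len, copies=copies,
                                     start=i, end=end))
                i = j  # a maximal run cannot restart inside itself
            else:
                i += 1
    # drop runs that are sub-periodic echoes of a shorter-unit locus
    # occupying the same span (e.g. an A-run rediscovered at unit 2 is
    # already excluded by primitivity; nothing further needed here)
    loci.sort(key=lambda l: (l.start, l.unit_len))
    if rec is not None and annotate and rec.features:
        for l in loci:
            l.region = classify_region(rec, l.start)
    elif rec is not None and rec.partition is not None:
        for l in loci:
            l.region = RegionLabel(
                "IGS", rec.partition.compartment_of(l.start), flanking="-")
    return loci


def ssr_summary(loci: list[SSRLocus],
                partition: Optional[QuadripartitePartition] = None
                ) -> pd.DataFrame:
    """Counts and percentages by motif class, functional region and
    compartment. IR-duplicated loci (same motif/copies at mirrored
    positions of IRa/IRb) are counted per physical copy and flagged."""
    if partition is not None:
        _flag_ir_duplicates(loci, partition)
    rows = []
    total = len(loci)

    def pct(k: int) -> float:
        return 100.0 * k / total if total else 0.0

    class_names = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta"}
    for unit_len, name in class_names.items():
        k = sum(l.unit_len == unit_len for l in loci)
        rows.append({"category": "class", "key": name,
                     "count": k, "percent": pct(k)})
    for func in ("CDS", "intron", "IGS"):
        k = sum(l.region is not None and l.region.functional == func
                for l in loci)
        rows.append({"category": "functional", "key": func,
                     "count": k, "percent": pct(k)})
    for comp in ("LSC", "IR", "SSC"):
        if comp == "IR":
            k = sum(l.region is not None
                    and l.region.compartment in ("IRa", "IRb") for l in loci)
        else:
            k = sum(l.region is not None and l.region.compartment == comp
                    for l in loci)
        rows.append({"category": "compartment", "key": comp,
                     "count": k, "percent": pct(k)})
    rows.append({"category": "total", "key": "all",
                 "count": total, "percent": 100.0 if total else 0.0})
    return pd.DataFrame(rows)


def _flag_ir_duplicates(loci: list[SSRLocus],
                        partition: QuadripartitePartition) -> None:
    irb, ira = partition.irb, partition.ira
    in_irb = [l for l in loci if irb[0] <= l.start < irb[1]]
    in_ira = [l for l in loci if ira[0] <= l.start < ira[1]]
    for lb in in_irb:
        # mirrored coordinate of the run start within IRa
        for la in in_ira:
            same = (la.unit_len == lb.unit_len and la.copies == lb.copies
                    and la.motif == canonical_motif(revcomp(lb.motif)))
            mirrored = (lb.start - irb[0]) == (ira[1] - la.end)
            if same and mirrored:
                la.ir_duplicate = lb.ir_duplicate = True


def ssr_locus_matrix(per_taxon_loci: dict[str, list[SSRLocus]],
                     alignment: Alignment) -> pd.DataFrame:
    """Match SSR loci (unit length >= 2) across taxa by alignment-column
    overlap and tabulate copy numbers with a per-locus status:
    conserved (identical in all taxa), autapomorphic (exactly one taxon
    deviates), synapomorphic otherwise."""
    row_of = {lab: i for i, lab in enumerate(alignment.labels)}
    items = []
    for taxon, loci in per_taxon_loci.items():
        row = row_of[taxon]
        for l in loci:
            if l.unit_len < 2:
                continue
            cols = frozenset(alignment.columns_for(row, l.start, l.end))
            items.append((taxon, l, cols))
    parent = list(range(len(items)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            if items[i][1].motif != items[j][1].motif:
                continue
            a, b = items[i][2], items[j][2]
            if a & b:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    clusters: dict[int, dict[str, int]] = {}
    meta: dict[int, tuple[int, str]] = {}
    for idx, (taxon, l, cols) in enumerate(items):
        root = find(idx)
        clusters.setdefault(root, {})[taxon] = l.copies
        meta.setdefault(root, (min(cols) if cols else 0, l.motif))
    taxa = list(per_taxon_loci)
    records = []
    for root in sorted(clusters, key=lambda r: meta[r][0]):
        copies = clusters[root]
        values = [copies.get(t, 0) for t in taxa]
        distinct: dict[int, int] = {}
        for v in values:
            distinct[v] = distinct.get(v, 0) + 1
        if len(distinct) == 1:
            status = "conserved"
        elif len(distinct) == 2 and min(distinct.values()) == 1:
            status = "autapomorphic"
        else:
            status = "synapomorphic"
        rec = {"column": meta[root][0], "motif": meta[root][1],
               "status": status}
        rec.update({t: copies.get(t, 0) for t in taxa})
        records.append(rec)
    return pd.DataFrame(records)
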