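"""Cross-species small-inversion (SI) calling.

An SI locus is a hairpin whose loop appears in opposite orientations in
different species: recombination between the stem arms reverse-
complements the loop (a flip-flop mutation) without touching flanking
sequence. Calling proceeds per taxon (hairpin detection on ungapped
sequences), then across taxa (grouping homologous loci by overlap of
their stem-arm alignment columns), then per locus (orientation of every
observed loop against the majority form).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from ._seq import edit_distance, infix_edit_distance, revcomp
from .hairpin import HairpinLocus, ThermoParams, find_hairpins, hairpin_delta_g
from .io import Alignment, classify_region
from .records import PlastomeRecord, RegionLabel


@dataclass
class OrientationCall:
    orientation: str               # A, B or ambiguous
    subtype: str = ""              # A1, A2, ..., B1, ...
    loop_seq_observed: str = ""
    stem_modified: bool = False

    def __post_init__(self) -> None:
        if self.subtype and self.orientation in ("A", "B") \
                and not self.subtype.startswith(self.orientation):
            raise ValueError("subtype prefix must match orientation")


@dataclass
class SIProfile:
    si_id: int
    region: Optional[RegionLabel]
    ref_stem_seq: str
    ref_loop_seq: str              # the A form
    delta_g: Optional[float] = None
    assignments: dict[str, OrientationCall] = field(default_factory=dict)
    position: Optional[int] = None     # genome_start in the reference taxon

    def orientation_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for call in self.assignments.values():
            counts[call.orientation] = counts.get(call.orientation, 0) + 1
        return counts

    def is_autapomorphic(self) -> bool:
        """Exactly one taxon carries the minority orientation (A/B only)."""
        c = self.orientation_counts()
        ab = sorted(c.get(s, 0) for s in ("A", "B"))
        return len([s for s in ("A", "B") if c.get(s, 0)]) == 2 and ab[0] == 1


def classify_orientation(ref_loop: str, observed_loop: str,
                         max_subtype_mismatch: int = 3) -> OrientationCall:
    """Orient an observed loop against the reference (A-form) loop.

    A if the observed loop is closer (Levenshtein) to the reference than
    to its reverse complement, B on the strict converse, ambiguous on a
    tie — which includes every loop that is its own reverse complement.
    """
    if not ref_loop or not observed_loop:
        raise ValueError("loops must be non-empty")
    ref_loop, observed_loop = ref_loop.upper(), observed_loop.upper()
    d_a = edit_distance(observed_loop, ref_loop)
    d_b = edit_distance(observed_loop, revcomp(ref_loop))
    if d_a < d_b:
        orientation = "A"
    elif d_b < d_a:
        orientation = "B"
    else:
        orientation = "ambiguous"
    return OrientationCall(orientation=orientation,
                           loop_seq_observed=observed_loop)


def closure_distance(a_loops: list[str], b_loop: str) -> int:
    """Smallest free-end-gap edit distance between a B loop and the
    reverse complement of any A loop (extra flanking bases in the longer
    sequence are not charged)."""
    best = None
    for a in a_loops:
        ra = revcomp(a)
        short, long_ = sorted((ra, b_loop.upper()), key=len)
        d = infix_edit_distance(short, long_)
        best = d if best is None else min(best, d)
    return best


def assign_subtypes(profile: SIProfile) -> None:
    """Number loop-sequence groups within each orientation by decreasing
    taxon count, then first occurrence, as A1, A2, ..., B1, ..."""
    for orient in ("A", "B"):
        groups: dict[str, list[str]] = {}
        order: dict[str, int] = {}
        for idx, (taxon, call) in enumerate(profile.assignments.items()):
            if call.orientation != orient:
                continue
            groups.setdefault(call.loop_seq_observed, []).append(taxon)
            order.setdefault(call.loop_seq_observed, idx)
        ranked = sorted(groups, key=lambda s: (-len(groups[s]), order[s]))
        for i, seq in enumerate(ranked, 1):
            label = f"{orient}{i}"
            for taxon in groups[seq]:
                profile.assignments[taxon].subtype = label


def _group_loci(per_taxon: dict[str, list[HairpinLocus]], alignment: Alignment,
                row_of: dict[str, int], min_jaccard: float = 0.5
                ) -> list[dict[str, HairpinLocus]]:
    """Cluster hairpins across taxa into homologous loci by Jaccard
    overlap (>= min_jaccard) of the alignment columns under their stem
    arms; single-linkage via union-find."""
    items: list[tuple[str, HairpinLocus, frozenset[int]]] = []
    for taxon, loci in per_taxon.items():
        row = row_of[taxon]
        for h in loci:
            cols = set(alignment.columns_for(row, h.genome_start, h.loop_start))
            cols |= set(alignment.columns_for(row, h.loop_end, h.genome_end))
            items.append((taxon, h, frozenset(cols)))
    parent = list(range(len(items)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            a, b = items[i][2], items[j][2]
            if not a or not b:
                continue
            inter = len(a & b)
            if inter and inter / len(a | b) >= min_jaccard:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    clusters: dict[int, dict[str, HairpinLocus]] = {}
    for idx, (taxon, h, _) in enumerate(items):
        root = find(idx)
        group = clusters.setdefault(root, {})
        # one hairpin per taxon per locus; keep the longer stem
        if taxon not in group or h.stem_len > group[taxon].stem_len:
            group[taxon] = h
    return list(clusters.values())


def call_si_loci(alignment: Alignment, records: list[PlastomeRecord],
                 hairpin_params: Optional[dict] = None,
                 min_taxa_with_stem: int = 15,
                 thermo: Optional[ThermoParams] = None) -> list[SIProfile]:
    """Detect SI loci across a set of aligned plastomes.

    Steps: per-taxon hairpin detection on ungapped sequences; homology
    grouping by stem-arm alignment-column overlap; majority-orientation
    reference (the A form; ties resolved toward the first taxon in input
    order); loci monomorphic in orientation are discarded; the region
    label is taken from the first record that carries annotation.
    """
    if alignment.n_rows != len(records):
        raise ValueError("alignment rows and records must correspond 1:1")
    labels = [r.taxon_label for r in records]
    if labels != alignment.labels:
        by_label = {lab: i for i, lab in enumerate(alignment.labels)}
        missing = [lab for lab in labels if lab not in by_label]
        if missing:
            raise ValueError(f"taxa missing from alignment: {missing}")
        alignment = Alignment(labels=labels,
                              rows=[alignment.rows[by_label[lab]]
                                    for lab in labels])
    row_of = {lab: i for i, lab in enumerate(labels)}
    hp = hairpin_params or {}
    per_taxon = {r.taxon_label: find_hairpins(
        alignment.ungapped(row_of[r.taxon_label]), **hp) for r in records}

    profiles: list[SIProfile] = []
    for group in _group_loci(per_taxon, alignment, row_of):
        if len(group) < min_taxa_with_stem:
            continue
        ordered = [t for t in labels if t in group]
        ref_taxon = ordered[0]
        provisional_ref = group[ref_taxon].loop_seq
        calls = {t: classify_orientation(provisional_ref, group[t].loop_seq)
                 for t in ordered}
        n_a = sum(c.orientation == "A" for c in calls.values())
        n_b = sum(c.orientation == "B" for c in calls.values())
        if n_a == 0 or n_b == 0:
            continue  # monomorphic in orientation: not an SI
        if n_b > n_a:  # majority carries the flipped form: relabel it A
            for c in calls.values():
                if c.orientation == "A":
                    c.orientation = "B"
                elif c.orientation == "B":
                    c.orientation = "A"
        a_taxa = [t for t in ordered if calls[t].orientation == "A"]
        ref_loop = group[a_taxa[0]].loop_seq
        ref_stem = group[a_taxa[0]].stem_seq
        region = None
        for rec in records:
            if rec.features:
                # map the loop start through the alignment into the
                # annotated record's own coordinates
                try:
                    col = alignment.seq_to_col(row_of[a_taxa[0]],
                                               group[a_taxa[0]].loop_start)
                    pos = alignment.col_to_seq(row_of[rec.taxon_label], col)
                    region = (classify_region(rec, pos) if pos >= 0 else None)
                except (IndexError, ValueError):
                    region = None
                break
        profile = SIProfile(si_id=0, region=region, ref_stem_seq=ref_stem,
                            ref_loop_seq=ref_loop, assignments=calls,
                            position=group[a_taxa[0]].genome_start)
        for t in ordered:
            calls[t].stem_modified = group[t].stem_seq != ref_stem
        profile.delta_g = hairpin_delta_g(group[a_taxa[0]], thermo)
        profiles.append(profile)

    profiles.sort(key=lambda p: p.position)
    for i, p in enumerate(profiles, 1):
        p.si_id = i
    return profiles


def si_report(profiles: list[SIProfile]) -> pd.DataFrame:
    """One row per (locus, subtype) with member taxa; stem-modified taxa
    flagged with a trailing '*'."""
    for p in profiles:
        if not all(c.subtype for c in p.assignments.values()
                   if c.orientation in ("A", "B")):
            assign_subtypes(p)
    rows = []
    for p in profiles:
        subtypes: dict[str, list[str]] = {}
        loops: dict[str, str] = {}
        for taxon, call in p.assignments.items():
            if call.orientation == "ambiguous":
                continue
            name = taxon + ("*" if call.stem_modified else "")
            subtypes.setdefault(call.subtype, []).append(name)
            loops[call.subtype] = call.loop_seq_observed
        for subtype in sorted(subtypes):
            rows.append({
                "si_id": p.si_id,
                "region": (p.region.flanking or p.region.functional)
                if p.region else "",
                "stem_seq": p.ref_stem_seq,
                "delta_g": p.delta_g,
                "subtype": subtype,
                "loop_seq": loops[subtype],
                "loop_len": len(loops[subtype]),
                "taxa": ",".join(subtypes[subtype]),
            })
    return pd.DataFrame(rows, columns=["si_id", "region", "stem_seq",
                                       "delta_g", "subtype", "loop_seq",
                                       "loop_len", "taxa"])


def si_character_matrix(profiles: list[SIProfile],
                        taxa: list[str]) -> pd.DataFrame:
    """Binary character matrix (taxa x loci) with states A/B/? for the
    parsimony mapper; '?' where a taxon lacks the stem or is ambiguous."""
    data = {}
    for p in profiles:
        col = []
        for t in taxa:
            call = p.assignments.get(t)
            col.append(call.orientation if call and call.orientation
                       in ("A", "B") else "?")
        data[f"si_{p.si_id}"] = col
    return pd.DataFrame(data, index=taxa)
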