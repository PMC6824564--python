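"""Stem-loop (hairpin) detection and nearest-neighbor free-energy scoring.

A hairpin here is a pair of short inverted-repeat arms (the stem)
flanking an unpaired apex (the loop). The flip-flop mutation of interest
reverse-complements the loop while leaving the stem intact, so the free
energy — a function of the stem pairs and the loop *length* only — is
identical for the two orientations. That exact symmetry is the model's
load-bearing property; absolute agreement with any particular folding
program's printed values is not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from ._seq import is_wc_pair, revcomp

# Unified DNA/DNA nearest-neighbor stack free energies at 37 C, kcal/mol,
# keyed by the 5'->3' dinucleotide on the top strand (SantaLucia-style
# unified parameter set; the ten unique duplex values expanded to all 16).
NN_STACK_DG37: dict[str, float] = {
    "AA": -1.00, "TT": -1.00,
    "AT": -0.88,
    "TA": -0.58,
    "CA": -1.45, "TG": -1.45,
    "GT": -1.44, "AC": -1.44,
    "CT": -1.28, "AG": -1.28,
    "GA": -1.30, "TC": -1.30,
    "CG": -2.17,
    "GC": -2.24,
    "GG": -1.84, "CC": -1.84,
}

# Hairpin-loop initiation penalties (kcal/mol) indexed by loop length;
# intermediate sizes are interpolated, larger ones extrapolated with the
# Jacobson-Stockmayer log term.
HAIRPIN_LOOP_DG37: dict[int, float] = {
    3: 3.5, 4: 3.5, 5: 3.3, 6: 4.0, 7: 4.1, 8: 4.1, 9: 4.2, 10: 4.3,
    12: 4.5, 14: 4.6, 16: 4.7, 18: 4.8, 20: 4.9, 25: 5.2, 30: 5.4,
}

_R_KCAL = 0.0019872  # gas constant, kcal/(mol*K)


@dataclass
class ThermoParams:
    """Nearest-neighbor parameter set: stacks plus loop-length penalty."""

    stack_energies: dict[str, float] = field(
        default_factory=lambda: dict(NN_STACK_DG37))
    hairpin_loop_penalty: dict[int, float] = field(
        default_factory=lambda: dict(HAIRPIN_LOOP_DG37))
    temperature: float = 37.0  # Celsius

    def loop_penalty(self, loop_len: int) -> float:
        table = self.hairpin_loop_penalty
        if loop_len in table:
            return table[loop_len]
        sizes = sorted(table)
        if loop_len < sizes[0]:
            return table[sizes[0]]
        if loop_len > sizes[-1]:
            t_kelvin = self.temperature + 273.15
            return table[sizes[-1]] + 1.75 * _R_KCAL * t_kelvin * math.log(
                loop_len / sizes[-1])
        lo = max(s for s in sizes if s < loop_len)
        hi = min(s for s in sizes if s > loop_len)
        w = (loop_len - lo) / (hi - lo)
        return table[lo] * (1 - w) + table[hi] * w


@dataclass
class HairpinLocus:
    """One detected stem-loop on a genome/sequence."""

    genome_start: int
    genome_end: int
    stem_len: int
    loop_start: int
    loop_end: int
    stem_seq: str          # 5' arm
    loop_seq: str
    mismatches_in_stem: int = 0
    delta_g: Optional[float] = None

    @property
    def loop_len(self) -> int:
        return self.loop_end - self.loop_start


def find_hairpins(seq: str, min_stem: int = 8, max_stem: int = 40,
                  min_loop: int = 4, max_loop: int = 30,
                  max_mismatch: int = 0) -> list[HairpinLocus]:
    """All maximal stem-loops in `seq` under the given arm/loop bounds.

    For every candidate loop interval the stem is extended outward base
    by base until the next pair fails with the mismatch budget spent, the
    sequence ends, or `max_stem` is reached; the innermost and outermost
    stem positions must pair, and at most `max_mismatch` interior
    positions may violate pairing. Among overlapping candidates whose
    loops intersect, those with a strictly shorter stem than a rival are
    suppressed. Result sorted by genome_start.
    """
    if min_stem < 4:
        raise ValueError("min_stem must be >= 4")
    seq = seq.upper()
    n = len(seq)
    candidates: list[HairpinLocus] = []
    for loop_start in range(1, n):
        max_ll = min(max_loop, n - loop_start - 1)
        for loop_len in range(min_loop, max_ll + 1):
            loop_end = loop_start + loop_len
            if not is_wc_pair(seq[loop_start - 1], seq[loop_end]):
                continue  # innermost stem pair must close the loop
            k, mm = 0, 0
            mm_at: list[int] = []
            while (loop_start - 1 - k >= 0 and loop_end + k < n
                   and k < max_stem):
                a, b = seq[loop_start - 1 - k], seq[loop_end + k]
                if is_wc_pair(a, b):
                    k += 1
                elif mm < max_mismatch:
                    mm += 1
                    mm_at.append(k)
                    k += 1
                else:
                    break
            # trim trailing mismatches: outermost position must pair
            while mm_at and mm_at[-1] == k - 1:
                mm_at.pop()
                k -= 1
            if k < min_stem:
                continue
            s = loop_start - k
            e = loop_end + k
            candidates.append(HairpinLocus(
                genome_start=s, genome_end=e, stem_len=k,
                loop_start=loop_start, loop_end=loop_end,
                stem_seq=seq[s:loop_start], loop_seq=seq[loop_start:loop_end],
                mismatches_in_stem=len(mm_at)))
    return _suppress_overlaps(candidates)


def _suppress_overlaps(candidates: list[HairpinLocus]) -> list[HairpinLocus]:
    # drop a candidate only when a strictly longer stem shares its loop
    # region; equal-stem rivals are both real structures, and keeping
    # them preserves exact reverse-complement symmetry of detection
    kept: list[HairpinLocus] = []
    for h in sorted(candidates,
                    key=lambda h: (-h.stem_len, h.genome_start, h.loop_start)):
        if any(h.loop_start < k.loop_end and k.loop_start < h.loop_end
               and k.stem_len > h.stem_len for k in kept):
            continue
        kept.append(h)
    kept.sort(key=lambda h: (h.genome_start, h.loop_start))
    return kept


def stem_duplex_dg(stem_seq: str, params: ThermoParams | None = None) -> float:
    """Stem-only duplex energy: sum of nearest-neighbor stacks along the
    5' arm paired with its reverse complement."""
    params = params or ThermoParams()
    if len(stem_seq) < 2:
        raise ValueError("stem too short to stack")
    return sum(params.stack_energies[stem_seq[i:i + 2]]
               for i in range(len(stem_seq) - 1))


def hairpin_delta_g(h: HairpinLocus, params: ThermoParams | None = None) -> float:
    """Full hairpin free energy: stem stacks + loop initiation penalty.

    Depends only on the stem sequence and loop length, hence exactly
    invariant under reverse-complementing the loop (the flip-flop
    neutrality property). Stores the value on the locus.
    """
    params = params or ThermoParams()
    dg = stem_duplex_dg(h.stem_seq, params) + params.loop_penalty(h.loop_len)
    h.delta_g = dg
    return dg


def hairpin_from_parts(stem_seq: str, loop_seq: str,
                       genome_start: int = 0) -> HairpinLocus:
    """Build a locus from an explicit 5' arm and loop (3' arm implied)."""
    s = genome_start
    ls = s + len(stem_seq)
    le = ls + len(loop_seq)
    return HairpinLocus(genome_start=s, genome_end=le + len(stem_seq),
                        stem_len=len(stem_seq), loop_start=ls, loop_end=le,
                        stem_seq=stem_seq.upper(), loop_seq=loop_seq.upper())


def hairpin_sequence(h: HairpinLocus) -> str:
    return h.stem_seq + h.loop_seq + revcomp(h.stem_seq)
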