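"""Detect the large inverted repeat pair of a plastome and partition the
circle into LSC / IRb / SSC / IRa.

Plastomes carry two exact, oppositely oriented copies of a ~20 kb repeat
(IRa/IRb) separating a large and a small single-copy region. Detection
here is exact-match: the longest segment whose reverse complement also
occurs elsewhere on the circle, found by binary search over the repeat
length with a rolling-hash table and direct string verification.
"""

from __future__ import annotations

from .records import PlastomeRecord, QuadripartitePartition
from ._seq import revcomp


class NoQuadripartiteStructure(ValueError):
    pass


def at_content(record: PlastomeRecord | str) -> float:
    """(A+T) / (A+C+G+T); N and other symbols are excluded entirely."""
    seq = record if isinstance(record, str) else record.sequence
    seq = seq.upper()
    at = seq.count("A") + seq.count("T")
    acgt = at + seq.count("C") + seq.count("G")
    if acgt == 0:
        raise ValueError("sequence has no A/C/G/T bases")
    return at / acgt


def _ir_hits(doubled: str, rc: str, n: int, length: int) -> list[tuple[int, int]]:
    """Start pairs (i, j) with doubled[i:i+length] == revcomp of the circle
    window starting at j; i, j in [0, n), i != j. `doubled` is the genome
    concatenated with itself so origin-spanning windows are visible; `rc`
    is its reverse complement."""
    table: dict[int, list[int]] = {}
    base, mod = 1114111, (1 << 61) - 1
    powl = pow(base, length - 1, mod)
    h = 0
    for c in doubled[:length]:
        h = (h * base + ord(c)) % mod
    table.setdefault(h, []).append(0)
    for i in range(1, n):
        h = ((h - ord(doubled[i - 1]) * powl) * base
             + ord(doubled[i + length - 1])) % mod
        table.setdefault(h, []).append(i)
    hits = []
    hr = 0
    for c in rc[:length]:
        hr = (hr * base + ord(c)) % mod
    # position k in rc corresponds to the circle window starting at
    # (2n - k - length) mod n on the forward strand
    for k in range(0, 2 * n - length + 1):
        if k > 0:
            hr = ((hr - ord(rc[k - 1]) * powl) * base
                  + ord(rc[k + length - 1])) % mod
        for i in table.get(hr, ()):
            j = (2 * n - k - length) % n
            if i == j:
                continue
            if doubled[i:i + length] == rc[k:k + length]:
                hits.append((i, j))
    return hits


def _geometry_ok(i: int, j: int, length: int, n: int) -> bool:
    """The two arcs [i, i+length) and [j, j+length) must be disjoint on the
    circle and leave two (possibly empty) single-copy arcs between them."""
    if 2 * length > n:
        return False
    gap1 = (j - (i + length)) % n
    gap2 = (i - (j + length)) % n
    return gap1 + gap2 == n - 2 * length


def detect_partition(record: PlastomeRecord,
                     min_ir_len: int = 10_000) -> QuadripartitePartition:
    """Find the maximal exact inverted-repeat pair and induce the four
    compartments. The larger single-copy arc is LSC. Deterministic
    tie-break: among maximal pairs, the one whose LSC starts earliest
    after canonical rotation (smallest IRb start following LSC).
    """
    seq = record.sequence
    n = len(seq)
    if n < 2 * min_ir_len:
        raise NoQuadripartiteStructure(
            f"{record.taxon_label}: no inverted repeat >= {min_ir_len} bp")
    doubled = seq + seq
    rc = revcomp(doubled)

    def hits_at(length: int) -> list[tuple[int, int]]:
        return [(i, j) for i, j in _ir_hits(doubled, rc, n, length)
                if _geometry_ok(i, j, length, n)]

    lo, hi = min_ir_len, n // 2
    if not hits_at(lo):
        raise NoQuadripartiteStructure(
            f"{record.taxon_label}: no inverted repeat >= {min_ir_len} bp")
    while lo < hi:  # largest length with a geometric hit
        mid = (lo + hi + 1) // 2
        if hits_at(mid):
            lo = mid
        else:
            hi = mid - 1
    ir_len = lo
    best = None
    for i, j in hits_at(ir_len):
        gap_after_i = (j - (i + ir_len)) % n   # arc between copy i and copy j
        gap_after_j = (i - (j + ir_len)) % n
        # label so that the longer single-copy arc (LSC) precedes IRb
        if gap_after_j >= gap_after_i:
            lsc_start, irb_start, ssc_len = (j + ir_len) % n, i, gap_after_i
            lsc_len = gap_after_j
        else:
            lsc_start, irb_start, ssc_len = (i + ir_len) % n, j, gap_after_j
            lsc_len = gap_after_i
        key = (lsc_start, irb_start)
        if best is None or key < best[0]:
            best = (key, lsc_start, irb_start, lsc_len, ssc_len)
    _, lsc_start, irb_start, lsc_len, ssc_len = best

    def arc(start: int, length: int) -> tuple[int, int]:
        return start % n, start % n + length

    part = QuadripartitePartition(
        lsc=arc(lsc_start, lsc_len),
        irb=arc(lsc_start + lsc_len, ir_len),
        ssc=arc(lsc_start + lsc_len + ir_len, ssc_len),
        ira=arc(lsc_start + lsc_len + ir_len + ssc_len, ir_len),
        at_content=at_content(record),
    )
    return part


def canonical_rotation(record: PlastomeRecord) -> PlastomeRecord:
    """Rotate the circle so LSC starts at position 0 (standard convention);
    detects the partition if the record has none. Features are dropped
    (coordinates would need remapping; rotation is used on plain genomes).
    """
    part = record.partition or detect_partition(record)
    n = record.length_bp
    shift = part.lsc[0] % n
    seq = record.sequence[shift:] + record.sequence[:shift]
    rotated = PlastomeRecord(taxon_label=record.taxon_label, sequence=seq)
    rotated.partition = detect_partition(rotated, min_ir_len=part.ir_len)
    return rotated
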