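"""Low-level sequence helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGT")


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_wc_pair(a: str, b: str) -> bool:
    """True if a/b form a Watson-Crick pair (no wobble, N never pairs)."""
    return (a == "A" and b == "T") or (a == "T" and b == "A") \
        or (a == "C" and b == "G") or (a == "G" and b == "C")


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance, plain DP. Loops compared here are <= ~30 bp."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def infix_edit_distance(query: str, target: str) -> int:
    """Best edit distance of `query` against any substring of `target`.

    Free end gaps on the target side only (semi-global alignment); used
    where one loop form carries extra flanking bases relative to the
    reverse complement of its counterpart.
    """
    if not query:
        return 0
    if not target:
        return len(query)
    prev = [0] * (len(target) + 1)          # free leading target gap
    for i, cq in enumerate(query, 1):
        cur = [i]
        for j, ct in enumerate(target, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (cq != ct)))
        prev = cur
    return min(prev)                         # free trailing target gap
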