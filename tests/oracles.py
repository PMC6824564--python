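"""Independent brute-force oracles used to cross-check the fast paths.

These re-derive expected results by exhaustive enumeration and share no
code with the implementations they check.
"""

from __future__ import annotations

from itertools import product

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _pairs(a: str, b: str) -> bool:
    return _COMP.get(a) == b


# ------------------------------------------------------------- hairpins

def brute_force_hairpins(seq: str, min_stem: int = 8, max_stem: int = 40,
                         min_loop: int = 4, max_loop: int = 30
                         ) -> list[tuple[int, int, int, int]]:
    """All maximal perfect stem-loops as (arm_start, stem_len,
    loop_start, loop_len), after the same loop-overlap suppression rule
    (longest stem wins, ties to leftmost), sorted by arm_start.
    Enumerates every (loop, stem) combination directly: O(n^3)."""
    n = len(seq)
    cands = []
    for loop_start in range(n):
        for loop_len in range(min_loop, max_loop + 1):
            loop_end = loop_start + loop_len
            for k in range(min_stem, max_stem + 1):
                s = loop_start - k
                e = loop_end + k
                if s < 0 or e > n:
                    continue
                if not all(_pairs(seq[loop_start - 1 - i], seq[loop_end + i])
                           for i in range(k)):
                    continue
                extendable = (k < max_stem and s - 1 >= 0 and e + 1 <= n
                              and _pairs(seq[s - 1], seq[e]))
                if extendable:
                    continue
                cands.append((s, k, loop_start, loop_len))
    kept: list[tuple[int, int, int, int]] = []
    for c in sorted(cands, key=lambda c: (-c[1], c[0], c[2])):
        ls, ll = c[2], c[3]
        if any(ls < k[2] + k[3] and k[2] < ls + ll and k[1] > c[1]
               for k in kept):
            continue
        kept.append(c)
    return sorted(kept)


# ----------------------------------------------------------------- SSRs

_THRESH = {1: 10, 2: 5, 3: 4, 4: 3, 5: 2}


def _primitive(motif: str) -> bool:
    return all(motif != motif[:p] * (len(motif) // p)
               for p in range(1, len(motif)) if len(motif) % p == 0)


def brute_force_ssrs(seq: str) -> list[tuple[int, int, int]]:
    """All qualifying maximal perfect repeats as (start, unit_len,
    copies); windows sharing a periodic run are reduced to the leftmost
    phase. Enumerates every window directly."""
    n = len(seq)
    windows = []
    for unit in range(1, 6):
        for start in range(n):
            motif = seq[start:start + unit]
            if len(motif) < unit or "N" in motif or not _primitive(motif):
                continue
            copies = 0
            while seq[start + copies * unit:
                      start + (copies + 1) * unit] == motif:
                copies += 1
            if copies < _THRESH[unit]:
                continue
            if start - unit >= 0 and seq[start - unit:start] == motif:
                continue  # extendable left by a full unit: not maximal
            windows.append((start, unit, copies))
    # same-period overlapping windows: keep the leftmost start
    kept = []
    for w in sorted(windows):
        start, unit, copies = w
        end = start + unit * copies
        clash = any(u == unit and s < end and start < s + u * c
                    for s, u, c in kept)
        if not clash:
            kept.append(w)
    return kept


# ---------------------------------------------------------------- Fitch

def brute_force_parsimony(children: dict, leaf_states: dict[str, str],
                          root: str) -> int:
    """Minimum number of A/B changes on a rooted tree by enumerating all
    internal-node assignments. `children[node]` lists child node ids;
    leaves (absent from `children`) carry states from `leaf_states`
    ('?' = free)."""
    internal = [v for v in children]
    best = None
    for combo in product("AB", repeat=len(internal)):
        assign = dict(zip(internal, combo))
        cost = 0
        stack = [root]
        while stack:
            v = stack.pop()
            for c in children.get(v, ()):
                if c in children:
                    cost += assign[v] != assign[c]
                    stack.append(c)
                else:
                    s = leaf_states.get(c, "?")
                    if s != "?":
                        cost += assign[v] != s
        if best is None or cost < best:
            best = cost
    return best


# ------------------------------------------------------------------- pi

def naive_pi_windows(rows: list[str], window: int, step: int
                     ) -> list[float | None]:
    """Window-by-window Nei average computed directly from strings."""
    n = len(rows)
    ncols = len(rows[0])
    out = []
    for start in range(0, ncols - window + 1, step):
        valid = [c for c in range(start, start + window)
                 if all(r[c] in "ACGT" for r in rows)]
        if not valid:
            out.append(None)
            continue
        total = 0
        npairs = 0
        for i in range(n):
            for j in range(i + 1, n):
                npairs += 1
                total += sum(rows[i][c] != rows[j][c] for c in valid)
        out.append(total / npairs / len(valid))
    return out
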