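"""Synthetic plastome datasets with fully known truth.

The generator assembles a quadripartite circular ancestor (LSC gene and
spacer blocks, an inverted-repeat pair, SSC blocks), plants hairpin loci
and perfect SSRs at chosen positions, then evolves the genome along a
given rooted tree under Jukes-Cantor substitution. Planted elements are
protected from substitution (documented simulation convenience; a
`hostile` flag lifts the protection to exercise stem-erosion handling),
loop orientations are reverse-complemented on chosen branches and
inherited by all descendants (two flips on a root-to-leaf path cancel),
and the two IR copies are kept identical within each taxon, emulating
concerted evolution. No indels are simulated, so the true alignment is
the sequences themselves, column-exact.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._seq import revcomp
from .char_evolution import RootedTree, read_newick
from .io import Alignment, write_genbank
from .records import Feature, PlastomeRecord, QuadripartitePartition

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_IDX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class GeneBlock:
    """One blueprint block: a named gene (optionally multi-exon) or an
    anonymous spacer. `exons` are intervals relative to the block."""

    name: str
    length: int
    kind: str = "spacer"               # gene | spacer
    exons: Optional[list[tuple[int, int]]] = None
    pseudo: bool = False


@dataclass
class PlantedHairpin:
    block: str
    offset: int                        # of the 5' arm start, within block
    stem: str
    loop: str
    flip_branches: list = field(default_factory=list)
    # each entry: a leaf label (terminal branch) or a tuple of leaf
    # labels (the branch above their MRCA)


@dataclass
class PlantedSSR:
    block: str
    offset: int
    motif: str
    copies: int


@dataclass
class SimConfig:
    seed: int
    newick: str
    lsc_blocks: list[GeneBlock]
    ssc_blocks: list[GeneBlock]
    ir_len: int = 300
    planted_hairpins: list[PlantedHairpin] = field(default_factory=list)
    planted_ssrs: list[PlantedSSR] = field(default_factory=list)
    hostile: bool = False              # lift substitution protection
    # relative substitution rate inside the inverted repeats; plastome IRs
    # evolve several-fold slower than single-copy regions because gene
    # conversion between the copies removes mutations
    ir_rate_scale: float = 0.3


@dataclass
class TruthTable:
    partition_lengths: dict[str, int]
    hairpins: list[dict]               # per planted locus: coords, truth
    ssrs: list[dict]
    taxa: list[str]

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=str)


class ConfigError(ValueError):
    pass


def _random_block(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length).astype(np.uint8)


def _scrub(seq: np.ndarray, rng: np.random.Generator,
           protected: np.ndarray) -> None:
    """Break background homopolymer/short-period runs so that no
    accidental SSR meets the class thresholds outside planted loci."""
    from .ssr import COPY_THRESHOLDS
    n = len(seq)
    changed = True
    while changed:
        changed = False
        for unit, min_copies in COPY_THRESHOLDS.items():
            limit = unit * min_copies
            i = unit
            run = unit
            while i < n:
                if seq[i] == seq[i - unit]:
                    run += 1
                    if run >= limit:
                        # break periodicity at any unprotected position
                        # of the run (runs may straddle planted elements)
                        for pos in range(i, i - limit, -1):
                            if protected[pos]:
                                continue
                            avoid = {seq[pos]}
                            if pos - unit >= 0:
                                avoid.add(seq[pos - unit])
                            if pos + unit < n:
                                avoid.add(seq[pos + unit])
                            options = [b for b in range(4) if b not in avoid]
                            if options:
                                seq[pos] = options[rng.integers(0, len(options))]
                                changed = True
                                break
                        run = unit
                else:
                    run = unit
                i += 1


def _to_str(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode()


def _encode(s: str) -> np.ndarray:
    return np.array([_IDX[c] for c in s.upper()], dtype=np.uint8)


def _clade_below(node) -> frozenset[str]:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def _resolve_branch(tree: RootedTree, spec) -> frozenset[str]:
    if isinstance(spec, str):
        if spec not in tree.leaf_labels:
            raise ConfigError(f"flip branch {spec!r} is not a leaf label")
        return frozenset([spec])
    want = set(spec)
    best = None
    for node in tree.tree.postorder_node_iter():
        clade = _clade_below(node)
        if want <= clade and (best is None or len(clade) < len(best)):
            best = clade
    if best is None:
        raise ConfigError(f"cannot resolve branch {spec!r}")
    return frozenset(best)


def _jc_mutate(seq: np.ndarray, t: float, rng: np.random.Generator,
               protected: np.ndarray,
               site_scale: np.ndarray | float = 1.0) -> np.ndarray:
    """One Jukes-Cantor step of expected length t substitutions/site,
    with optional per-site rate multipliers."""
    out = seq.copy()
    if t <= 0:
        return out
    p_stay = 0.25 + 0.75 * np.exp(-4.0 * t * site_scale / 3.0)
    mutate = (rng.random(len(seq)) > p_stay) & ~protected
    idx = np.nonzero(mutate)[0]
    if len(idx):
        out[idx] = (out[idx] + rng.integers(1, 4, size=len(idx))) % 4
    return out


def simulate_dataset(config: SimConfig
                     ) -> tuple[list[PlastomeRecord], Alignment, TruthTable]:
    """Build the ancestor, evolve it along the tree, and return records,
    the exact alignment and the truth table. Deterministic under seed."""
    rng = np.random.default_rng(config.seed)
    tree = read_newick(config.newick)

    # ---- assemble ancestor and coordinate bookkeeping
    block_start: dict[str, int] = {}
    features: list[Feature] = []
    parts: list[np.ndarray] = []
    pos = 0

    def add_blocks(blocks: Sequence[GeneBlock]) -> None:
        nonlocal pos
        for b in blocks:
            if b.name in block_start:
                raise ConfigError(f"duplicate block name {b.name!r}")
            block_start[b.name] = pos
            parts.append(_random_block(rng, b.length))
            if b.kind == "gene":
                iv = ([(pos + s, pos + e) for s, e in b.exons]
                      if b.exons else [(pos, pos + b.length)])
                for s, e in iv:
                    if not (pos <= s < e <= pos + b.length):
                        raise ConfigError(f"exons of {b.name!r} exceed block")
                features.append(Feature(kind="gene", name=b.name,
                                        intervals=iv, pseudo=b.pseudo))
            pos += b.length

    add_blocks(config.lsc_blocks)
    lsc_len = pos
    irb = _random_block(rng, config.ir_len)
    block_start["IRb"] = pos
    parts.append(irb)
    pos += config.ir_len
    ssc_start = pos
    add_blocks(config.ssc_blocks)
    ssc_len = pos - ssc_start
    block_start["IRa"] = pos
    ira = _encode(revcomp(_to_str(irb)))
    parts.append(ira)
    pos += config.ir_len
    ancestor = np.concatenate(parts)
    n = len(ancestor)

    partition = QuadripartitePartition(
        lsc=(0, lsc_len), irb=(lsc_len, lsc_len + config.ir_len),
        ssc=(ssc_start, ssc_start + ssc_len),
        ira=(ssc_start + ssc_len, n))

    # junction guards: stop the exact inverted repeat from extending past
    # the planted boundaries by chance complementarity. Extension pairs
    # (last LSC base, first genome base) and (first SSC base, last SSC
    # base); an A opposite an A never pairs. Guarded positions are also
    # protected from substitution below.
    junction_guards = [0, lsc_len - 1, ssc_start, ssc_start + ssc_len - 1]
    for g in junction_guards:
        ancestor[g] = _IDX["A"]

    # ---- plant elements (with 1 bp non-pairing guards around hairpins)
    protected = np.zeros(n, dtype=bool)
    protected[junction_guards] = True
    hairpin_truth: list[dict] = []
    occupied: list[tuple[int, int]] = []

    def claim(s: int, e: int, what: str) -> None:
        for a, b in occupied:
            if s < b and a < e:
                raise ConfigError(f"planted elements overlap at {what}")
        if e > n or s < 0:
            raise ConfigError(f"{what} outside genome")
        occupied.append((s, e))

    for ph in config.planted_hairpins:
        if ph.block not in block_start or ph.block in ("IRa",):
            raise ConfigError(f"unknown or invalid block {ph.block!r}")
        start = block_start[ph.block] + ph.offset
        construct = ph.stem + ph.loop + revcomp(ph.stem)
        s, e = start - 1, start + len(construct) + 1   # guards included
        claim(s, e, f"hairpin in {ph.block!r}")
        ancestor[start:start + len(construct)] = _encode(construct)
        # guard bases: A next to the arms never pairs with A
        ancestor[s] = _IDX["A"]
        ancestor[e - 1] = _IDX["A"]
        protected[s:e] = True
        loop_start = start + len(ph.stem)
        hairpin_truth.append({
            "block": ph.block, "start": start,
            "loop_start": loop_start, "loop_end": loop_start + len(ph.loop),
            "stem": ph.stem.upper(), "loop": ph.loop.upper(),
            "flip_clades": [sorted(_resolve_branch(tree, b))
                            for b in ph.flip_branches],
            "n_flip_branches": len(ph.flip_branches),
        })

    ssr_truth: list[dict] = []
    for ps in config.planted_ssrs:
        start = block_start[ps.block] + ps.offset
        run = ps.motif.upper() * ps.copies
        s, e = start - 1, start + len(run) + 1
        claim(s, e, f"SSR in {ps.block!r}")
        ancestor[start:start + len(run)] = _encode(run)
        # guards stop accidental extension of the planted run
        ancestor[s] = _IDX["G"] if ps.motif.upper()[-1] != "G" else _IDX["C"]
        ancestor[e - 1] = _IDX["G"] if ps.motif.upper()[0] != "G" else _IDX["C"]
        protected[s:e] = True
        ssr_truth.append({"block": ps.block, "start": start,
                          "end": start + len(run), "motif": ps.motif.upper(),
                          "copies": ps.copies})

    _scrub(ancestor, rng, protected)
    if config.hostile:
        protected = np.zeros(n, dtype=bool)

    # ---- evolve along the tree
    flip_specs = [
        {frozenset(_resolve_branch(tree, b)) for b in ph.flip_branches}
        for ph in config.planted_hairpins]
    leaf_seqs: dict[str, np.ndarray] = {}
    leaf_flip_parity: dict[str, list[int]] = {}

    site_scale = np.ones(n)
    site_scale[lsc_len:lsc_len + config.ir_len] = config.ir_rate_scale
    site_scale[ssc_start + ssc_len:n] = config.ir_rate_scale

    def descend(node, seq: np.ndarray, parity: list[int]) -> None:
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            cseq = _jc_mutate(seq, t, rng, protected, site_scale)
            cparity = list(parity)
            clade = _clade_below(child)
            for k, specs in enumerate(flip_specs):
                if clade in specs:
                    ht = hairpin_truth[k]
                    ls, le = ht["loop_start"], ht["loop_end"]
                    cseq[ls:le] = _encode(revcomp(_to_str(cseq[ls:le])))
                    cparity[k] ^= 1
            if child.is_leaf():
                label = child.taxon.label
                final = cseq.copy()
                # concerted evolution: IRa mirrors IRb exactly
                final[ssc_start + ssc_len:n] = _encode(
                    revcomp(_to_str(final[lsc_len:lsc_len + config.ir_len])))
                leaf_seqs[label] = final
                leaf_flip_parity[label] = cparity
            else:
                descend(child, cseq, cparity)

    descend(tree.root, ancestor,
            [0] * len(config.planted_hairpins))

    taxa = tree.leaf_labels
    records = []
    for label in taxa:
        rec = PlastomeRecord(taxon_label=label,
                             sequence=_to_str(leaf_seqs[label]),
                             features=[Feature(f.kind, f.name,
                                               list(f.intervals), f.strand,
                                               f.pseudo)
                                       for f in features])
        rec.partition = partition
        records.append(rec)
    alignment = Alignment(labels=taxa, rows=[r.sequence for r in records])

    for k, ht in enumerate(hairpin_truth):
        orientations = {label: ("B" if leaf_flip_parity[label][k] else "A")
                        for label in taxa}
        n_b = sum(v == "B" for v in orientations.values())
        n_a = len(taxa) - n_b
        # name the majority form A, as the caller does; on an exact tie
        # the first taxon's form is A (also the caller's rule)
        if n_b > n_a or (n_b == n_a and orientations[taxa[0]] == "B"):
            orientations = {t: ("A" if v == "B" else "B")
                            for t, v in orientations.items()}
            n_a, n_b = n_b, n_a
        ht["orientations"] = orientations
        ht["is_si"] = n_a > 0 and n_b > 0
        ht["autapomorphic"] = min(n_a, n_b) == 1 and ht["is_si"]

    truth = TruthTable(
        partition_lengths={"lsc": lsc_len, "ir": config.ir_len,
                           "ssc": ssc_len, "total": n},
        hairpins=hairpin_truth, ssrs=ssr_truth, taxa=taxa)
    return records, alignment, truth


def survey_like_config(seed: int = 0) -> SimConfig:
    """A 20-taxon configuration mirroring the statistical structure of
    the published Lauraceae survey: eleven planted hairpin loci whose
    stems and loops are the curated reference constructs, with flips
    placed so that five loci are autapomorphic (one flip on a terminal
    branch) and six are polymorphic with multiple flips; perfect SSRs of
    each motif class; genes named after the real flanking genes so the
    region labels of the planted loci match the published ones.
    """
    from .datasets import load_si_survey

    taxa = [f"s{i:02d}" for i in range(1, 21)]
    L = 0.004

    def cherry(a: str, b: str) -> str:
        return f"({a}:{L},{b}:{L}):{L}"

    # balanced-ish rooted 20-taxon tree
    quads = [cherry(cherry(taxa[i], taxa[i + 1]),
                    cherry(taxa[i + 2], taxa[i + 3]))
             for i in range(0, 20, 4)]
    newick = (f"(({quads[0]},{quads[1]}):{L},"
              f"(({quads[2]},{quads[3]}):{L},{quads[4]}):{L});")

    survey = load_si_survey()
    stems = {loc.number: loc.stem for loc in survey}
    loops = {loc.number: loc.a_loops()[0] for loc in survey}

    lsc_blocks = [
        GeneBlock("trnH", 120, "gene"), GeneBlock("sp_hp1", 420),
        GeneBlock("psbA", 260, "gene"), GeneBlock("rps16", 220, "gene"),
        GeneBlock("sp_hp3", 300), GeneBlock("trnQ", 90, "gene"),
        GeneBlock("rpoB", 400, "gene"), GeneBlock("sp_hp4", 320),
        GeneBlock("trnC", 90, "gene"), GeneBlock("psbC", 350, "gene"),
        GeneBlock("sp_hp5", 300), GeneBlock("trnS", 90, "gene"),
        GeneBlock("petA", 300, "gene"), GeneBlock("sp_hp67", 520),
        GeneBlock("psbJ", 140, "gene"), GeneBlock("rpoA", 500, "gene"),
        GeneBlock("sp_ssr", 600),
    ]
    ssc_blocks = [
        GeneBlock("ccsA", 280, "gene"), GeneBlock("sp_hp10", 320),
        GeneBlock("ndhD", 280, "gene"),
        GeneBlock("ndhA", 620, "gene", exons=[(0, 200), (420, 620)]),
        GeneBlock("ycf2", 400, "gene"),
    ]

    # single-taxon flips (autapomorphies) for loci 3, 4, 5, 8, 9;
    # multi-branch flips for the six others
    hairpins = [
        PlantedHairpin("sp_hp1", 40, stems[1], loops[1],
                       [("s01", "s02"), "s07", "s15"]),
        PlantedHairpin("sp_hp1", 200, stems[2], loops[2],
                       [("s05", "s06", "s07", "s08"), "s11"]),
        PlantedHairpin("sp_hp3", 60, stems[3], loops[3], ["s03"]),
        PlantedHairpin("sp_hp4", 80, stems[4], loops[4], ["s10"]),
        PlantedHairpin("sp_hp5", 80, stems[5], loops[5], ["s17"]),
        PlantedHairpin("sp_hp67", 60, stems[6], loops[6],
                       [("s09", "s10"), "s14", "s20"]),
        PlantedHairpin("sp_hp67", 260, stems[7], loops[7],
                       [("s13", "s14", "s15", "s16"), "s02"]),
        PlantedHairpin("rpoA", 200, stems[8], loops[8], ["s06"]),
        PlantedHairpin("ycf2", 150, stems[9], loops[9], ["s12"]),
        PlantedHairpin("sp_hp10", 60, stems[10], loops[10],
                       [("s17", "s18", "s19", "s20"), "s04", "s08"]),
        PlantedHairpin("ndhA", 250, stems[11], loops[11],
                       [("s01", "s02", "s03", "s04"), "s18"]),
    ]
    ssrs = [
        PlantedSSR("sp_ssr", 20, "A", 12),
        PlantedSSR("sp_ssr", 60, "T", 10),
        PlantedSSR("sp_ssr", 100, "AT", 6),
        PlantedSSR("sp_ssr", 140, "AAG", 4),
        PlantedSSR("sp_ssr", 180, "AATC", 3),
        PlantedSSR("sp_ssr", 240, "AATAG", 2),
        PlantedSSR("sp_hp3", 200, "A", 11),
        PlantedSSR("sp_hp4", 220, "TA", 5),
    ]
    return SimConfig(seed=seed, newick=newick, lsc_blocks=lsc_blocks,
                     ssc_blocks=ssc_blocks, ir_len=1000,
                     planted_hairpins=hairpins, planted_ssrs=ssrs)


def make_fixture_genbank(config: SimConfig,
                         outdir: str | os.PathLike) -> list[str]:
    """Simulate and write one annotated GenBank file per taxon."""
    records, _, _ = simulate_dataset(config)
    os.makedirs(outdir, exist_ok=True)
    paths = []
    for rec in records:
        path = os.path.join(str(outdir), f"{rec.taxon_label}.gb")
        write_genbank(rec, path)
        paths.append(path)
    return paths
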