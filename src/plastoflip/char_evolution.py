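"""Binary character mapping on a rooted tree: Fitch parsimony with
ACCTRAN resolution, per-branch change lists, and character status
(invariant / autapomorphic / synapomorphic).

States are {A, B}; '?' is missing and is treated as the unrestricted set
in the bottom-up pass. Polytomies are allowed: the Fitch sets generalize
to multi-child intersection/union. Among equally parsimonious
reconstructions, ACCTRAN places state changes on the most rootward
admissible branches; for a binary character the only reconstruction
freedom is the root state, which is chosen to give the rootmost change
profile (final tie: state A).
"""

from __future__ import annotations

import io as _io
import os
from dataclasses import dataclass, field
from typing import Optional

import dendropy
import pandas as pd


@dataclass
class RootedTree:
    """Thin wrapper over a dendropy tree with deterministic child order
    (children sorted by their smallest descendant leaf label)."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for leaf in self.tree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon else None
            if not label:
                raise ValueError("unlabeled leaf in tree")
            if label in seen:
                raise ValueError(f"duplicate leaf label {label!r}")
            seen.add(label)
        self._canonicalize()

    def _canonicalize(self) -> None:
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                node._min_leaf = node.taxon.label
            else:
                node._child_nodes.sort(key=lambda c: c._min_leaf)
                node._min_leaf = node._child_nodes[0]._min_leaf

    @property
    def leaf_labels(self) -> list[str]:
        return [l.taxon.label for l in self.tree.leaf_node_iter()]

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def branch_name(self, node: dendropy.Node) -> str:
        """Stable identifier of the branch above `node`: the sorted leaf
        set below it, abbreviated to the smallest leaf + subtree size."""
        leaves = sorted(l.taxon.label for l in node.leaf_iter())
        if len(leaves) == 1:
            return leaves[0]
        return f"{leaves[0]}+{len(leaves) - 1}"


def read_newick(path_or_str: str | os.PathLike,
                outgroup: Optional[str] = None) -> RootedTree:
    """Read a newick tree; optionally (re)root on a named outgroup leaf."""
    src = str(path_or_str)
    if os.path.exists(src):
        tree = dendropy.Tree.get(path=src, schema="newick")
    else:
        tree = dendropy.Tree.get(file=_io.StringIO(src), schema="newick")
    if outgroup is not None:
        node = None
        for leaf in tree.leaf_node_iter():
            if leaf.taxon and leaf.taxon.label == outgroup:
                node = leaf
                break
        if node is None:
            raise ValueError(f"outgroup {outgroup!r} not found in tree")
        tree.reroot_at_edge(node.edge, update_bipartitions=False)
    return RootedTree(tree)


def write_newick(tree: RootedTree, path: str | os.PathLike) -> None:
    tree.tree.write(path=str(path), schema="newick",
                    suppress_rooting=True)


@dataclass
class Change:
    branch: str
    from_state: str
    to_state: str
    depth: int  # edges from the root to the child end of the branch


def _uppass(tree: RootedTree, sets: dict, root_state: str,
            states: dict[str, str]) -> list[Change]:
    assigned: dict = {tree.root: root_state}
    changes: list[Change] = []
    for node in tree.tree.preorder_node_iter():
        if node is tree.root:
            node._depth = 0
            continue
        node._depth = node.parent_node._depth + 1
        p = assigned[node.parent_node]
        s = sets[node]
        chosen = p if p in s else sorted(s)[0]
        if node.is_leaf() and states.get(node.taxon.label, "?") == "?":
            chosen = p  # missing leaf: inherit, no change
        assigned[node] = chosen
        if chosen != p:
            changes.append(Change(tree.branch_name(node), p, chosen,
                                  node._depth))
    return changes


def fitch_acctran(tree: RootedTree,
                  character: dict[str, str]) -> tuple[int, list[Change]]:
    """Minimum change count and an ACCTRAN change list for one binary
    character. Raises if a scored taxon is absent from the tree, or if
    no taxon has a non-missing state.
    """
    leaf_labels = set(tree.leaf_labels)
    extra = [t for t in character if t not in leaf_labels]
    if extra:
        raise ValueError(f"taxa not in tree: {extra}")
    observed = {s for s in character.values() if s != "?"}
    if not observed:
        raise ValueError("character has no non-missing state")
    if not observed <= {"A", "B"}:
        raise ValueError(f"states must be in {{A, B, ?}}, got {observed}")

    sets: dict = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            s = character.get(node.taxon.label, "?")
            sets[node] = frozenset("AB") if s == "?" else frozenset(s)
        else:
            inter = frozenset("AB")
            for c in node.child_nodes():
                inter &= sets[c]
            if inter:
                sets[node] = inter
            else:
                union = frozenset()
                for c in node.child_nodes():
                    union |= sets[c]
                sets[node] = union

    root_set = sets[tree.root]
    # deterministic, relabeling-symmetric anchor for root-state ties:
    # the state of the first non-missing leaf in canonical order
    anchor = next(s for s in (character.get(l.taxon.label, "?")
                              for l in tree.tree.leaf_node_iter())
                  if s != "?")
    best = None
    for root_state in sorted(root_set):
        changes = _uppass(tree, sets, root_state, character)
        # rootward preference: lexicographically smallest depth profile
        profile = tuple(sorted(c.depth for c in changes))
        key = (len(changes), profile, root_state != anchor)
        if best is None or key < best[0]:
            best = (key, changes)
    changes = best[1]
    return len(changes), changes


@dataclass
class CharacterMap:
    """Character matrix + tree + per-character parsimony results."""

    matrix: pd.DataFrame          # taxa x characters, states A/B/?
    tree: RootedTree
    lengths: dict[str, int] = field(default_factory=dict)
    changes: dict[str, list[Change]] = field(default_factory=dict)
    status: dict[str, str] = field(default_factory=dict)

    @classmethod
    def fit(cls, matrix: pd.DataFrame, tree: RootedTree) -> "CharacterMap":
        cmap = cls(matrix=matrix, tree=tree)
        for char in matrix.columns:
            states = {t: str(matrix.loc[t, char]) for t in matrix.index}
            cmap.lengths[char], cmap.changes[char] = fitch_acctran(tree, states)
            cmap.status[char] = character_status(states)
        return cmap


def character_status(states: dict[str, str]) -> str:
    counts: dict[str, int] = {}
    for s in states.values():
        if s in ("A", "B"):
            counts[s] = counts.get(s, 0) + 1
    if len(counts) <= 1:
        return "invariant"
    if min(counts.values()) == 1:
        return "autapomorphic"
    return "synapomorphic"


def classify_characters(cmap: CharacterMap) -> pd.DataFrame:
    """Per-character summary: status, change counts split by direction,
    and (as frame attrs) the change-count range over synapomorphic
    characters."""
    rows = []
    for char in cmap.matrix.columns:
        ch = cmap.changes[char]
        rows.append({
            "character": char,
            "status": cmap.status[char],
            "parsimony_length": cmap.lengths[char],
            "a_to_b": sum(c.from_state == "A" and c.to_state == "B"
                          for c in ch),
            "b_to_a": sum(c.from_state == "B" and c.to_state == "A"
                          for c in ch),
        })
    df = pd.DataFrame(rows)
    syn = df[df["status"] == "synapomorphic"]["parsimony_length"]
    df.attrs["synapomorphic_min_changes"] = int(syn.min()) if len(syn) else 0
    df.attrs["synapomorphic_max_changes"] = int(syn.max()) if len(syn) else 0
    return df
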