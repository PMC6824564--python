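import numpy as np
import pandas as pd
import pytest

from oracles import brute_force_parsimony
from plastoflip import (CharacterMap, classify_characters, fitch_acctran,
                        read_newick)


def _random_tree(rng, n_leaves):
    """Random rooted binary tree as (newick, children-dict, root)."""
    nodes = [f"t{i}" for i in range(n_leaves)]
    newicks = {n: n for n in nodes}
    children = {}
    counter = [0]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]   # pop higher index first
        internal = f"n{counter[0]}"
        counter[0] += 1
        children[internal] = [a, b]
        newicks[internal] = f"({newicks[a]},{newicks[b]})"
        nodes = [n for n in nodes if n not in (a, b)] + [internal]
    root = nodes[0]
    return newicks[root] + ";", children, root


class TestReadNewick:
    def test_four_taxon_topology(self):
        tree = read_newick("((a,b),(c,d));")
        assert sorted(tree.leaf_labels) == ["a", "b", "c", "d"]
        internal = sum(1 for n in tree.tree.preorder_node_iter()
                       if not n.is_leaf())
        assert internal == 3

    def test_outgroup_rooting(self):
        tree = read_newick("((a,b),(c,d));", outgroup="d")
        root_children = tree.root.child_nodes()
        clades = [sorted(l.taxon.label for l in c.leaf_iter())
                  for c in root_children]
        assert ["d"] in clades

    def test_missing_outgroup_fatal(self):
        with pytest.raises(ValueError, match="zzz"):
            read_newick("((a,b),(c,d));", outgroup="zzz")

    def test_round_trip_preserves_topology(self, tmp_path):
        from plastoflip.char_evolution import write_newick
        tree = read_newick("((a,(b,e)),(c,d));")
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        bip = lambda t: {  # noqa: E731
            frozenset(l.taxon.label for l in n.leaf_iter())
            for n in t.tree.preorder_node_iter()}
        assert bip(back) == bip(tree)


class TestFitchAcctran:
    def test_single_internal_change(self):
        tree = read_newick("((w,x),(y,z));")
        length, changes = fitch_acctran(
            tree, {"w": "A", "x": "A", "y": "B", "z": "B"})
        assert length == len(changes) == 1
        assert changes[0].depth == 1   # on an internal branch at the root

    def test_autapomorphy_changes_on_terminal_branch(self):
        tree = read_newick("((w,x),(y,z));")
        length, changes = fitch_acctran(
            tree, {"w": "A", "x": "A", "y": "A", "z": "B"})
        assert length == 1
        assert changes[0].branch == "z"
        assert (changes[0].from_state, changes[0].to_state) == ("A", "B")

    def test_caterpillar_alternating_states(self):
        nwk = "(((((((t0,t1),t2),t3),t4),t5),t6),t7);"
        tree = read_newick(nwk)
        states = {f"t{i}": "AB"[i % 2] for i in range(8)}
        length, changes = fitch_acctran(tree, states)
        children = {"n0": ["t0", "t1"]}
        for i in range(2, 8):
            children[f"n{i - 1}"] = [f"n{i - 2}", f"t{i}"]
        assert length == len(changes)
        assert length == brute_force_parsimony(children, states, "n6")

    def test_matches_exhaustive_minimum_on_random_trees(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            n = int(rng.integers(4, 13))
            nwk, children, root = _random_tree(rng, n)
            tree = read_newick(nwk)
            states = {f"t{i}": "AB?"[rng.integers(0, 3)] for i in range(n)}
            if all(s == "?" for s in states.values()):
                states["t0"] = "A"
            length, changes = fitch_acctran(tree, states)
            assert length == len(changes)
            assert length == brute_force_parsimony(children, states, root)

    def test_state_relabeling_swaps_directions(self):
        tree = read_newick("(((a,b),(c,d)),(e,f));")
        states = {"a": "A", "b": "B", "c": "B", "d": "B", "e": "A", "f": "A"}
        swapped = {t: {"A": "B", "B": "A"}[s] for t, s in states.items()}
        l1, c1 = fitch_acctran(tree, states)
        l2, c2 = fitch_acctran(tree, swapped)
        assert l1 == l2
        assert sorted((c.branch, c.from_state) for c in c1) \
            == sorted((c.branch, c.to_state) for c in c2)

    def test_missing_states_are_free(self):
        tree = read_newick("((w,x),(y,z));")
        length, _ = fitch_acctran(tree, {"w": "A", "x": "?", "y": "?",
                                         "z": "B"})
        assert length == 1

    def test_polytomy_supported(self):
        tree = read_newick("((a,b,c,d),(e,f));")
        length, _ = fitch_acctran(
            tree, {"a": "A", "b": "A", "c": "A", "d": "B", "e": "A",
                   "f": "A"})
        assert length == 1

    def test_unknown_taxon_fatal(self):
        tree = read_newick("((w,x),(y,z));")
        with pytest.raises(ValueError, match="qq"):
            fitch_acctran(tree, {"qq": "A", "w": "B"})

    def test_all_missing_fatal(self):
        tree = read_newick("((w,x),(y,z));")
        with pytest.raises(ValueError):
            fitch_acctran(tree, {"w": "?"})


class TestClassifyCharacters:
    def test_invariant_matrix(self):
        tree = read_newick("((w,x),(y,z));")
        matrix = pd.DataFrame({"c1": ["A"] * 4, "c2": ["B"] * 4},
                              index=["w", "x", "y", "z"])
        df = classify_characters(CharacterMap.fit(matrix, tree))
        assert (df["status"] == "invariant").all()
        assert (df["parsimony_length"] == 0).all()

    def test_single_deviant_taxon_is_autapomorphic(self):
        tree = read_newick("((w,x),(y,z));")
        matrix = pd.DataFrame({"c1": ["A", "A", "A", "B"]},
                              index=["w", "x", "y", "z"])
        df = classify_characters(CharacterMap.fit(matrix, tree))
        assert df.loc[0, "status"] == "autapomorphic"
        assert df.loc[0, "parsimony_length"] == 1

    def test_planted_flip_branches_recovered(self, survey_like_dataset):
        from conftest import survey_like_config
        from plastoflip import call_si_loci, si_character_matrix

        records, aln, truth = survey_like_dataset
        profiles = call_si_loci(aln, records)
        tree = read_newick(survey_like_config(seed=1).newick)
        matrix = si_character_matrix(profiles, truth.taxa)
        df = classify_characters(CharacterMap.fit(matrix, tree))
        for _, row in df.iterrows():
            si_id = int(row["character"].split("_")[1])
            profile = [p for p in profiles if p.si_id == si_id][0]
            # match planted locus by position (detected stems may differ
            # by a base when loop ends happen to pair)
            truth_h = min(truth.hairpins,
                          key=lambda h: abs(h["start"] - profile.position))
            assert row["parsimony_length"] == truth_h["n_flip_branches"]
            want = ("autapomorphic" if truth_h["autapomorphic"]
                    else "synapomorphic")
            assert row["status"] == want
        assert (df["status"] == "autapomorphic").sum() == 5
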