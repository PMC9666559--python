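"""Clade tests and placement-category classification."""

import pytest

import stemphylo as sp
from stemphylo import hypothesis as H
from stemphylo import parsimony as P
from stemphylo.nexus_io import TreeRecord

from conftest import random_binary_tree, splits_by_enumeration


class TestContainsClade:
    def test_direct_examples(self):
        t = sp.tree_from_newick("((Opa,Uta,CB),(R1,D1),OG);")
        assert H.contains_clade(t, {"Opa", "Uta", "CB"}, {"OG"})
        assert not H.contains_clade(t, {"Opa", "CB"}, {"OG"})

    def test_overlap_rejected(self):
        t = sp.tree_from_newick("((A,B),(C,D));")
        with pytest.raises(ValueError):
            H.contains_clade(t, {"A", "B"}, {"B", "C"})

    def test_members_restricted_to_present_taxa(self):
        t = sp.tree_from_newick("((A,B),(C,D),E);")
        # X is absent: membership restricts to {A, B}
        assert H.contains_clade(t, {"A", "B", "X"}, {"E"})

    def test_agrees_with_split_enumeration(self, rng):
        names = [f"x{i}" for i in range(10)]
        for _ in range(20):
            t = random_binary_tree(names, rng)
            splits = splits_by_enumeration(t)
            leaves = t.leaf_names
            members = frozenset(
                str(n) for n in rng.choice(names[:-1], size=3, replace=False)
            )
            og = frozenset({names[-1]}) - members
            want = False
            for s in splits | {frozenset({n}) for n in names}:
                for side in (s, leaves - s):
                    if side == members and og <= leaves - side:
                        want = True
            assert H.contains_clade(t, members, og) == want

    def test_rerooting_invariance(self, rng):
        # the same unrooted topology written with different rootings
        a = sp.tree_from_newick("((Opa,(Uta,CB)),((R1,R2),(D1,D2)),OG);")
        b = sp.tree_from_newick("(OG,(((R1,R2),(D1,D2)),(Opa,(Uta,CB))));")
        for members in ({"Opa", "Uta", "CB"}, {"R1", "R2", "D1", "D2"}):
            assert (H.contains_clade(a, members, {"OG"})
                    == H.contains_clade(b, members, {"OG"}))


class TestClassifyTree:
    def test_monophyletic(self, toy_defs):
        t = sp.tree_from_newick("((Opa,Uta,CB),((R1,R2),(D1,D2)),OG);")
        assert H.classify_tree(t, toy_defs).category == "monophyletic_proboscis"

    def test_paraphyletic(self, toy_defs):
        t = sp.tree_from_newick("((Opa,Uta),(CB,((R1,R2),(D1,D2))),OG);")
        assert H.classify_tree(t, toy_defs).category == "paraphyletic_grade"

    def test_other_with_subcategory(self, toy_defs):
        t = sp.tree_from_newick("((Opa,(Uta,(R1,CB))),(D1,D2),(R2,OG));")
        cat = H.classify_tree(t, toy_defs)
        assert cat.category == "other"
        assert "smallest_clade=2" in cat.subcategory
        assert "radiodonts" in cat.subcategory

    def test_missing_taxa_error(self, toy_defs):
        t = sp.tree_from_newick("((Opa,Uta),(R1,R2),OG);")
        with pytest.raises(ValueError, match="CB"):
            H.classify_tree(t, toy_defs)

    def test_mutual_exclusivity_exhaustive_eight_leaves(self, toy_defs):
        """On every binary 8-leaf topology the monophyletic-proboscis and
        paraphyletic-grade patterns never hold simultaneously."""
        names = ["Opa", "Uta", "CB", "R1", "R2", "D1", "D2", "OG"]
        defs = toy_defs
        n_mono = n_para = 0
        for t in P.all_unrooted_topologies(names):
            mono = H.contains_clade(t, defs.castle_bank | defs.opabiniids,
                                    defs.outgroup)
            para = H.contains_clade(
                t, defs.castle_bank | defs.radiodonts | defs.deuteropods,
                defs.outgroup)
            assert not (mono and para)
            n_mono += mono
            n_para += para
        assert n_mono > 0 and n_para > 0  # both patterns occur

    def test_unknown_scheme(self, toy_defs):
        t = sp.tree_from_newick("((Opa,Uta,CB),(R1,R2),(D1,(D2,OG)));")
        with pytest.raises(ValueError):
            H.classify_tree(t, toy_defs, scheme="loose")


class TestTwoTerminalRule:
    def _defs(self):
        return H.CladeDefinitions(
            opabiniids=frozenset({"Opa", "Uta"}),
            radiodonts=frozenset({"R1"}),
            deuteropods=frozenset({"D1"}),
            castle_bank=frozenset({"CB1", "CB2"}),
            outgroup=frozenset({"OG"}),
        )

    def test_both_terminals_required(self):
        defs = self._defs()
        both = sp.tree_from_newick("(((CB1,CB2),(Opa,Uta)),(R1,D1),OG);")
        split = sp.tree_from_newick("((CB1,(Opa,Uta)),(CB2,(R1,D1)),OG);")
        assert H.classify_tree(both, defs).category == "monophyletic_proboscis"
        assert H.classify_tree(split, defs).category == "other"


class TestTabulate:
    def _sample(self, defs, mono, para, other):
        trees = []
        trees += [sp.tree_from_newick("((Opa,Uta,CB),((R1,R2),(D1,D2)),OG);")] * mono
        trees += [sp.tree_from_newick("((Opa,Uta),(CB,((R1,R2),(D1,D2))),OG);")] * para
        trees += [sp.tree_from_newick("((Opa,(Uta,(R1,CB))),(D1,D2),(R2,OG));")] * other
        return [TreeRecord(t) for t in trees]

    def test_simple_percentages(self, toy_defs):
        table = H.tabulate_proportions(
            {"a": self._sample(toy_defs, 0, 6, 4)}, toy_defs
        )
        pct = table.percentages("a")
        assert pct["paraphyletic_grade"] == 60.0
        assert pct["other"] == 40.0

    def test_pooled_is_weighted_mean(self, toy_defs):
        samples = {
            "a": self._sample(toy_defs, 2, 6, 2),  # 10 trees, 60% para
            "b": self._sample(toy_defs, 15, 5, 0),  # 20 trees, 25% para
        }
        table = H.tabulate_proportions(samples, toy_defs, pooled=True)
        pooled = table.percentages("POOLED")
        assert pooled["paraphyletic_grade"] == pytest.approx(
            100 * (6 + 5) / 30, abs=0.05
        )

    def test_counts_sum_to_n(self, toy_defs):
        table = H.tabulate_proportions(
            {"a": self._sample(toy_defs, 3, 4, 5)}, toy_defs
        )
        row = table.table.iloc[0]
        counts = sum(row[f"count_{c}"] for c in H.CATEGORIES)
        assert counts == row["n_trees"] == 12

    def test_order_invariance(self, toy_defs, rng):
        trees = self._sample(toy_defs, 3, 5, 2)
        perm = [trees[i] for i in rng.permutation(len(trees))]
        t1 = H.tabulate_proportions({"a": trees}, toy_defs).percentages("a")
        t2 = H.tabulate_proportions({"a": perm}, toy_defs).percentages("a")
        assert t1 == t2

    def test_empty_sample_rejected(self, toy_defs):
        with pytest.raises(ValueError):
            H.tabulate_proportions({"a": []}, toy_defs)


class TestCladeDefinitions:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            H.CladeDefinitions(
                opabiniids=frozenset({"A"}), radiodonts=frozenset({"A"}),
                deuteropods=frozenset({"B"}), castle_bank=frozenset({"C"}),
                outgroup=frozenset({"D"}),
            )

    def test_from_matrix_and_rename(self, fixture_suite):
        m = fixture_suite.paper_shaped_matrix
        defs = H.CladeDefinitions.from_matrix(m)
        assert "castle_bank1" in defs.castle_bank
        renamed = defs.rename("castle_bank1", "cb_merged")
        assert "cb_merged" in renamed.castle_bank
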