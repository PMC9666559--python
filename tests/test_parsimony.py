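"""Fitch counting, implied weighting, search and consensus."""

import math

import pytest

import stemphylo as sp
from stemphylo.nexus_io import CellState, MISSING, CharacterMatrix
from stemphylo import parsimony as P

from conftest import (
    brute_force_fitch,
    random_binary_tree,
    random_column,
    random_matrix,
)


def obs(*states):
    return [CellState.observed(s) for s in states]


class TestFitchSteps:
    def test_constant_column_zero(self):
        t = sp.tree_from_newick("((A,B),(C,D));")
        assert P.fitch_steps(t, obs(0, 0, 0, 0), "ABCD") == 0

    def test_split_dependence(self):
        col = obs(0, 0, 1, 1)
        assert P.fitch_steps(sp.tree_from_newick("((A,B),(C,D));"), col, "ABCD") == 1
        assert P.fitch_steps(sp.tree_from_newick("((A,C),(B,D));"), col, "ABCD") == 2

    def test_missing_leaf_never_increases_steps(self, rng):
        names = [f"x{i}" for i in range(6)]
        for _ in range(20):
            t = random_binary_tree(names, rng)
            col = random_column(rng, 6, k=3, p_missing=0.0, p_poly=0.0)
            base = P.fitch_steps(t, col, names)
            i = int(rng.integers(6))
            col2 = list(col)
            col2[i] = MISSING
            assert P.fitch_steps(t, col2, names) <= base

    def test_matches_enumeration_with_ambiguity(self, rng):
        names = [f"x{i}" for i in range(6)]
        for _ in range(30):
            t = random_binary_tree(names, rng)
            col = random_column(rng, 6, k=3, p_missing=0.2, p_poly=0.15)
            assert P.fitch_steps(t, col, names) == brute_force_fitch(t, col, names)

    def test_leaf_without_cell_errors(self):
        t = sp.tree_from_newick("((A,B),(C,D));")
        with pytest.raises(ValueError):
            P.fitch_steps(t, obs(0, 0, 1), "ABC")


class TestCharMinSteps:
    @pytest.mark.parametrize(
        "column,expected",
        [
            (obs(0, 0, 1, 1), 1),
            ([MISSING] * 4, 0),
            (obs(0, 1, 2) + [CellState.polymorphic({0, 1})], 2),
            ([CellState.polymorphic({0, 1}), CellState.polymorphic({1, 2})], 0),
        ],
    )
    def test_examples(self, column, expected):
        assert P.char_min_steps(column) == expected

    def test_lower_bounds_fitch_on_any_tree(self, rng):
        names = [f"x{i}" for i in range(6)]
        for _ in range(25):
            t = random_binary_tree(names, rng)
            col = random_column(rng, 6, k=4, p_missing=0.2, p_poly=0.2)
            assert P.fitch_steps(t, col, names) >= P.char_min_steps(col)


class TestImpliedFit:
    def test_exact_values(self):
        assert P.implied_fit(0, 3) == 1.0
        assert P.implied_fit(3, 3) == 0.5
        assert P.implied_fit(1, 3) == 0.75

    def test_monotonicity(self):
        fits = [P.implied_fit(e, 3) for e in range(6)]
        assert all(a > b for a, b in zip(fits, fits[1:]))
        assert P.implied_fit(2, 5) > P.implied_fit(2, 3)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            P.implied_fit(-1, 3)


class TestScoreTree:
    def test_congruent_matrix_attains_nchar(self):
        t = sp.tree_from_newick("((A,B),(C,D));")
        m = CharacterMatrix(
            taxon_names=list("ABCD"),
            cells=[obs(0, 0), obs(0, 0), obs(1, 1), obs(1, 1)],
        )
        sc = P.score_tree(t, m, 3.0)
        assert sc.fit_total == pytest.approx(m.nchar)
        assert sc.distortion_total == pytest.approx(0.0)

    def test_fit_plus_distortion_identity(self, rng):
        for _ in range(10):
            m = random_matrix(rng, 6, 12, k=3, p_missing=0.2, p_poly=0.1)
            t = random_binary_tree(m.taxon_names, rng)
            sc = P.score_tree(t, m, 3.0)
            assert sc.fit_total + sc.distortion_total == pytest.approx(m.nchar)

    def test_leaf_mismatch_errors(self, rng):
        m = random_matrix(rng, 5, 4)
        t = random_binary_tree([f"y{i}" for i in range(5)], rng)
        with pytest.raises(ValueError):
            P.score_tree(t, m, 3.0)


class TestSearch:
    def test_best_matches_exhaustive_on_six_taxa(self, rng):
        m = random_matrix(rng, 6, 12, k=2, p_missing=0.1, p_poly=0.0)
        best_exh = max(
            P.score_tree(t, m, 3.0).fit_total
            for t in P.all_unrooted_topologies(m.taxon_names)
        )
        res = P.search_mp(m, P.SearchSettings(required_hits=3,
                                              n_random_addition_starts=20, seed=7))
        assert res.best_score.fit_total == pytest.approx(best_exh, abs=1e-9)

    def test_perfect_data_recovers_generating_topology(self, rng):
        # build a matrix whose characters are all congruent with one tree
        names = [f"x{i}" for i in range(7)]
        truth = random_binary_tree(names, rng)
        cols = []
        for split in truth.splits():
            cols.append([CellState.observed(1 if n in split else 0) for n in names])
        cols = cols * 4
        m = CharacterMatrix(
            taxon_names=names,
            cells=[[col[i] for col in cols] for i in range(7)],
        )
        res = P.search_mp(m, P.SearchSettings(required_hits=3,
                                              n_random_addition_starts=20, seed=1))
        assert res.best_score.fit_total == pytest.approx(m.nchar)
        assert any(t.splits() == truth.splits() for t in res.trees)

    def test_same_seed_same_result(self, rng):
        m = random_matrix(rng, 6, 10, k=2)
        ss = P.SearchSettings(required_hits=2, n_random_addition_starts=10, seed=42)
        r1 = P.search_mp(m, ss)
        r2 = P.search_mp(m, ss)
        assert [t.to_newick() for t in r1] == [t.to_newick() for t in r2]

    def test_equal_weights_agrees_without_homoplasy(self, rng):
        names = [f"x{i}" for i in range(6)]
        truth = random_binary_tree(names, rng)
        cols = [
            [CellState.observed(1 if n in split else 0) for n in names]
            for split in truth.splits()
        ] * 3
        m = CharacterMatrix(taxon_names=names,
                            cells=[[c[i] for c in cols] for i in range(6)])
        res_iw = P.search_mp(m, P.SearchSettings(concavity_k=3.0, required_hits=2,
                                                 n_random_addition_starts=10, seed=3))
        res_ew = P.search_mp(m, P.SearchSettings(concavity_k=math.inf, required_hits=2,
                                                 n_random_addition_starts=10, seed=3))
        assert {t.splits() for t in res_iw} == {t.splits() for t in res_ew}
        assert res_ew.best_score.steps_total == len(truth.splits()) * 3

    def test_too_few_taxa(self, rng):
        m = random_matrix(rng, 3, 4)
        with pytest.raises(ValueError):
            P.search_mp(m, P.SearchSettings())

    def test_budget_exhaustion_flagged(self, rng):
        m = random_matrix(rng, 6, 10, k=2)
        with pytest.warns(UserWarning, match="budget exhausted"):
            res = P.search_mp(m, P.SearchSettings(required_hits=50,
                                                  n_random_addition_starts=2, seed=0))
        assert res.budget_exhausted


class TestStrictConsensus:
    def test_identical_trees(self):
        t = sp.tree_from_newick("((A,B),(C,D),E);")
        cons = P.strict_consensus([t, t.copy()])
        assert cons.splits() == t.splits()

    def test_partial_agreement(self):
        a = sp.tree_from_newick("((A,B),(C,D),E);")
        b = sp.tree_from_newick("((A,B),(C,E),D);")
        cons = P.strict_consensus([a, b])
        # only the A|B split survives (canonical side excludes leaf A)
        assert cons.splits() == frozenset({frozenset({"C", "D", "E"})})

    def test_total_conflict_gives_star(self):
        a = sp.tree_from_newick("((A,B),(C,D));")
        b = sp.tree_from_newick("((A,C),(B,D));")
        cons = P.strict_consensus([a, b])
        assert cons.splits() == frozenset()

    def test_leaf_mismatch(self):
        a = sp.tree_from_newick("((A,B),(C,D));")
        b = sp.tree_from_newick("((A,B),(C,E));")
        with pytest.raises(ValueError):
            P.strict_consensus([a, b])
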