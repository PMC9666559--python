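"""Synthetic-data generator: trees, characters, missingness, fixtures."""

import numpy as np
import pytest
from scipy.stats import chisquare

import stemphylo as sp
from stemphylo import hypothesis as H, synthdata as S


class TestYuleTree:
    def test_leaf_count_and_binary(self):
        rec = S.simulate_yule_tree(5, seed=2)
        t = rec.tree
        assert t.n_leaves == 5
        assert t.is_binary()
        assert len(t.adj) == 5 + 3  # unrooted binary: n - 2 internal nodes

    def test_branch_lengths_positive(self):
        t = S.simulate_yule_tree(10, seed=3).tree
        assert all(t.edge_length(u, v) > 0 for (u, v) in t.edges())

    def test_constraints_enforced(self):
        rec = S.simulate_yule_tree(
            10, constraints={"grp": ["A", "B", "C"]}, seed=4
        )
        assert H.contains_clade(rec.tree, {"A", "B", "C"}, {"t1"})

    def test_determinism(self):
        a = S.simulate_yule_tree(8, seed=9).to_newick()
        b = S.simulate_yule_tree(8, seed=9).to_newick()
        assert a == b

    def test_unsatisfiable_constraints(self):
        with pytest.raises(ValueError):
            S.simulate_yule_tree(4, constraints={"g": ["a", "b", "c", "d", "e"]})
        with pytest.raises(ValueError):
            S.simulate_yule_tree(6, constraints={"g": []})


class TestSimulateCharacters:
    def test_zero_rate_all_constant(self):
        rec = S.simulate_yule_tree(6, seed=5)
        m = S.simulate_characters(rec, 25, {2: 1.0}, char_rate=0.0, seed=5)
        for j in range(m.nchar):
            assert len(m.observed_states(j)) == 1

    def test_saturation_approaches_uniform(self):
        """At branch lengths >> 1 the leaf states should be uniform."""
        rec = S.simulate_yule_tree(4, seed=6)
        t = rec.tree
        for (u, v) in t.edges():
            t.set_edge_length(u, v, 25.0)
        m = S.simulate_characters(rec, 10_000, {2: 1.0}, char_rate=1.0, seed=6)
        counts = np.zeros(2)
        for row in m.cells:
            for c in row:
                counts[next(iter(c.states))] += 1
        assert chisquare(counts).pvalue > 0.001

    def test_two_leaf_match_probability(self):
        """Fraction of identical leaf pairs matches the closed form P_same."""
        import math

        from stemphylo.nexus_io import Tree, TreeRecord

        t = Tree()
        a = t.new_node("A")
        b = t.new_node("B")
        tlen = 0.6
        t.add_edge(a, b, tlen)
        m = S.simulate_characters(TreeRecord(t), 5000, {2: 1.0}, 1.0, seed=7)
        same = sum(
            m.cells[0][j] == m.cells[1][j] for j in range(m.nchar)
        ) / m.nchar
        p_same = 0.5 + 0.5 * math.exp(-2 * tlen)
        se = math.sqrt(p_same * (1 - p_same) / 5000)
        assert abs(same - p_same) < 4 * se

    def test_state_count_distribution_respected(self):
        rec = S.simulate_yule_tree(12, seed=8)
        m = S.simulate_characters(rec, 300, {2: 0.5, 4: 0.5}, 0.5, seed=8)
        maxstates = [max(m.observed_states(j)) for j in range(m.nchar)]
        assert any(s >= 2 for s in maxstates)  # some 4-state characters drawn


class TestMissingness:
    def test_zero_rate_identity(self, fixture_suite):
        m = S.simulate_characters(S.simulate_yule_tree(6, seed=1), 10, {2: 1.0},
                                  0.4, seed=1)
        m2 = S.apply_missingness(m, [], 0.0, 0.0, seed=1)
        assert m2 == m

    def test_full_fossil_missing(self):
        m = S.simulate_characters(S.simulate_yule_tree(6, seed=2), 10, {2: 1.0},
                                  0.4, seed=2)
        fossils = m.taxon_names[:3]
        m2 = S.apply_missingness(m, fossils, 1.0, 0.0, seed=2)
        for t in fossils:
            assert all(c.kind == "missing" for c in m2.row(t))

    def test_realised_fraction_concentrates(self):
        rec = S.simulate_yule_tree(46, seed=3)
        m = S.simulate_characters(rec, 129, {2: 1.0}, 0.4, seed=3)
        m2 = S.apply_missingness(m, m.taxon_names, 0.5, 0.0, seed=3)
        counts = m2.cell_kind_counts()
        frac = counts["missing"] / (46 * 129)
        assert 0.48 <= frac <= 0.52  # 3 binomial SDs around 0.5


class TestMissingnessDegradesRecovery:
    def test_mean_rf_increases_with_missingness(self):
        """Simulation/inference consistency: adding 50% missing cells can
        only hurt topology recovery on average (10 seeds, small scale)."""
        from stemphylo import mk_mcmc as M
        from stemphylo.treespace import rf_distance

        rfs = {0.0: [], 0.5: []}
        for seed in range(10):
            rec = S.simulate_yule_tree(8, seed=50 + seed)
            t = rec.tree
            for (u, v) in t.edges():
                t.set_edge_length(u, v, 0.15)
            m0 = S.simulate_characters(rec, 150, {2: 1.0}, 1.0, seed=50 + seed)
            for f in (0.0, 0.5):
                m = (S.apply_missingness(m0, m0.taxon_names, f, f, seed=seed)
                     if f else m0)
                cfg = M.MkModelConfig(gamma_rate_variation=False,
                                      ascertainment="none", seed=70 + seed)
                rs = M.RunSettings(n_runs=1, n_chains_per_run=1,
                                   n_generations=3000, sample_every=20)
                cons = M.majority_consensus(M.run_mcmc(m, cfg, rs))
                rfs[f].append(rf_distance(cons.tree, rec.tree))
        assert np.mean(rfs[0.0]) <= np.mean(rfs[0.5])


class TestCategorySample:
    def test_mixture_recovered_within_three_percent(self, toy_defs):
        mixture = {"monophyletic_proboscis": 0.6, "paraphyletic_grade": 0.3,
                   "other": 0.1}
        trees, truth = S.simulate_category_tree_sample(
            toy_defs, mixture, n=1000, free_taxa=["F1", "F2"], seed=11
        )
        cats = [H.classify_tree(t, toy_defs).category for t in trees]
        assert cats == truth  # generator and classifier agree tree by tree
        for cat, p in mixture.items():
            assert abs(cats.count(cat) / 1000 - p) <= 0.03

    def test_bad_mixture_rejected(self, toy_defs):
        with pytest.raises(ValueError):
            S.simulate_category_tree_sample(toy_defs, {"other": 0.5}, 10)


class TestFixtureSuite:
    def test_study_shape(self, fixture_suite):
        m = fixture_suite.paper_shaped_matrix
        assert (m.ntax, m.nchar) == (57, 129)
        flags = list(m.taxon_flags.values())
        assert flags.count("extant") == 11 and flags.count("fossil") == 46
        assert set(m.group_map) == {
            "outgroup", "opabiniids", "castle_bank", "radiodonts", "deuteropods"
        }

    def test_missingness_concentrated_in_fossils(self, fixture_suite):
        m = fixture_suite.paper_shaped_matrix
        fossil = set(m.fossil_taxa())
        miss_f = miss_e = n_f = n_e = 0
        for t, row in zip(m.taxon_names, m.cells):
            miss = sum(c.kind == "missing" for c in row)
            if t in fossil:
                miss_f, n_f = miss_f + miss, n_f + len(row)
            else:
                miss_e, n_e = miss_e + miss, n_e + len(row)
        assert miss_f / n_f > 3 * (miss_e / n_e)

    def test_manifest_supports_rf_to_truth(self, fixture_suite):
        from stemphylo.treespace import rf_distance

        (rec,) = sp.parse_trees(fixture_suite.manifest["generating_tree_newick"])
        assert rf_distance(rec.tree, fixture_suite.generating_tree.tree) == 0

    def test_write_round_trip(self, fixture_suite, tmp_path):
        fixture_suite.write(tmp_path)
        m = sp.parse_matrix((tmp_path / "paper_shaped.nex").read_text())
        assert m == fixture_suite.paper_shaped_matrix
        trees = sp.parse_trees((tmp_path / "category_sample.nwk").read_text())
        assert len(trees) == len(fixture_suite.category_sample)
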