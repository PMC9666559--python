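"""Matrix variant construction: merging, taxon additions, convergence."""

import pytest

from stemphylo import recode as R
from stemphylo.nexus_io import CellState, INAPPLICABLE, MISSING, CharacterMatrix

def obs(s):
    return CellState.observed(s)


@pytest.fixture()
def tiny():
    return CharacterMatrix(
        taxon_names=["a", "b", "c", "d"],
        cells=[
            [obs(0), MISSING, obs(1)],
            [obs(1), obs(0), obs(1)],
            [obs(0), obs(0), INAPPLICABLE],
            [obs(1), obs(1), obs(0)],
        ],
        group_map={"castle_bank": frozenset({"a", "b"})},
        taxon_flags={"a": "fossil", "b": "fossil", "c": "extant", "d": "extant"},
    )


class TestMergeTerminals:
    def test_gap_absorbed(self, tiny):
        with pytest.warns(R.MergeConflictWarning):
            m = R.merge_terminals(tiny, "a", "b", "ab")
        row = m.row("ab")
        assert row[1] == obs(0)  # missing absorbed by the observed cell

    def test_conflict_becomes_polymorphic_with_warning(self, tiny):
        with pytest.warns(R.MergeConflictWarning, match="characters \\[1\\]"):
            m = R.merge_terminals(tiny, "a", "b", "ab")
        assert m.row("ab")[0] == CellState.polymorphic({0, 1})

    def test_counts_and_metadata(self, tiny):
        with pytest.warns(R.MergeConflictWarning):
            m = R.merge_terminals(tiny, "a", "b", "ab")
        assert m.ntax == tiny.ntax - 1
        assert m.group_map["castle_bank"] == frozenset({"ab"})
        assert m.taxon_flags["ab"] == "fossil"

    def test_symmetry(self, tiny):
        with pytest.warns(R.MergeConflictWarning):
            m1 = R.merge_terminals(tiny, "a", "b", "ab")
        with pytest.warns(R.MergeConflictWarning):
            m2 = R.merge_terminals(tiny, "b", "a", "ab")
        assert m1.cells == m2.cells

    def test_study_sized_merge(self, fixture_suite):
        base = fixture_suite.paper_shaped_matrix
        m = R.merge_terminals(base, "castle_bank1", "castle_bank2", "castle_bank_sp")
        assert (m.ntax, m.nchar) == (56, 129)

    def test_unknown_taxon(self, tiny):
        with pytest.raises(ValueError):
            R.merge_terminals(tiny, "a", "zz", "x")


class TestAddSensitivityTaxon:
    def test_append_without_extra_char(self, tiny):
        m = R.add_sensitivity_taxon(tiny, "new", [obs(0)] * 3, groups=("castle_bank",))
        assert m.ntax == 5 and m.nchar == 3
        assert "new" in m.group_map["castle_bank"]

    def test_extra_character_inserted_with_defaults(self, tiny):
        scoring = [obs(0)] * 4
        m = R.add_sensitivity_taxon(
            tiny, "new", scoring,
            extra_char=R.ExtraCharacter(index=1, default=MISSING, label="char55"),
        )
        assert m.nchar == 4
        assert m.row("a")[1] == MISSING  # pre-existing taxa get the default
        assert m.char_labels[1] == "char55"

    def test_all_missing_taxon_valid(self, tiny):
        m = R.add_sensitivity_taxon(tiny, "ghost", [MISSING] * 3)
        assert all(c == MISSING for c in m.row("ghost"))

    def test_two_scoring_variants_differ_only_where_configured(self, tiny):
        proto = [obs(0), obs(0), obs(1)]
        deuto = [obs(0), obs(1), obs(1)]  # differs at character 2 only
        m1 = R.add_sensitivity_taxon(tiny, "pp", proto)
        m2 = R.add_sensitivity_taxon(tiny, "pp", deuto)
        diffs = [j for j in range(3) if m1.row("pp")[j] != m2.row("pp")[j]]
        assert diffs == [1]

    def test_study_sized_addition(self, fixture_suite):
        base = fixture_suite.paper_shaped_matrix
        m = R.add_sensitivity_taxon(base, "kylinxia", [MISSING] * 129)
        m = R.add_sensitivity_taxon(
            m, "parapeytoia", [MISSING] * 130,
            extra_char=R.ExtraCharacter(index=54, default=MISSING, label="char55"),
        )
        assert (m.ntax, m.nchar) == (59, 130)

    def test_length_mismatch(self, tiny):
        with pytest.raises(ValueError):
            R.add_sensitivity_taxon(tiny, "new", [obs(0)] * 2)


class TestConvergenceRecoding:
    def _plan(self, m, features):
        actions = R.default_feature_actions(
            carapace_char=0, spines_char=1, rays_char=2,
            focal_group="castle_bank",
            rays_observed=m.observed_states(2) or {0},
        )
        return R.RecodingPlan(convergent_features=features, feature_actions=actions)

    def test_split_moves_focal_scorings(self, tiny):
        var = R.apply_convergence_recoding(tiny, self._plan(tiny, ("carapace",)))
        m = var.matrix
        assert m.nchar == 4
        assert m.row("a")[0] == INAPPLICABLE  # focal blanked on the original
        assert m.row("a")[1] == obs(0)  # focal keeps scoring on the copy
        assert m.row("c")[1] == INAPPLICABLE  # others inapplicable on the copy

    def test_add_state_rewrites_focal_only(self, tiny):
        var = R.apply_convergence_recoding(tiny, self._plan(tiny, ("strengthening_rays",)))
        m = var.matrix
        assert m.nchar == 3
        assert m.row("b")[2] == obs(2)  # derived state 1 -> new state 2
        assert m.row("d")[2] == tiny.row("d")[2]  # non-focal untouched

    def test_new_state_collision_rejected(self, tiny):
        actions = {"strengthening_rays": R.FeatureAction(
            "add_state", 2, "castle_bank", new_state=1)}
        plan = R.RecodingPlan(convergent_features=("strengthening_rays",),
                              feature_actions=actions)
        with pytest.raises(ValueError):
            R.apply_convergence_recoding(tiny, plan)

    @pytest.mark.parametrize(
        "features,expected_nchar",
        [
            (("carapace", "proboscis_dorsal_spines", "strengthening_rays"), 131),
            (("carapace",), 130),
            (("proboscis_dorsal_spines",), 130),
            (("strengthening_rays",), 129),
        ],
    )
    def test_study_character_counts(self, fixture_suite, features, expected_nchar):
        base = fixture_suite.paper_shaped_matrix
        actions = R.default_feature_actions(
            carapace_char=3, spines_char=17, rays_char=42,
            focal_group="castle_bank", rays_observed=base.observed_states(42),
        )
        plan = R.RecodingPlan(convergent_features=features, feature_actions=actions)
        var = R.apply_convergence_recoding(base, plan)
        assert var.matrix.nchar == expected_nchar

    def test_character_count_arithmetic_property(self, rng, fixture_suite):
        base = fixture_suite.paper_shaped_matrix
        for features in [(), ("carapace",), ("carapace", "strengthening_rays"),
                         ("carapace", "proboscis_dorsal_spines")]:
            actions = R.default_feature_actions(
                carapace_char=5, spines_char=30, rays_char=60,
                focal_group="castle_bank", rays_observed=base.observed_states(60),
            )
            plan = R.RecodingPlan(convergent_features=features,
                                  feature_actions=actions)
            var = R.apply_convergence_recoding(base, plan)
            assert var.matrix.nchar - base.nchar == plan.n_split_actions

    def test_non_focal_rows_never_change_on_original_chars(self, fixture_suite):
        base = fixture_suite.paper_shaped_matrix
        actions = R.default_feature_actions(
            carapace_char=3, spines_char=17, rays_char=42,
            focal_group="castle_bank", rays_observed=base.observed_states(42),
        )
        plan = R.RecodingPlan(
            convergent_features=("carapace", "proboscis_dorsal_spines",
                                 "strengthening_rays"),
            feature_actions=actions,
        )
        var = R.apply_convergence_recoding(base, plan)
        focal = base.group_map["castle_bank"]
        inserted = {4, 19}  # copies land after the split characters 3 and 17
        for t in base.taxon_names:
            if t in focal:
                continue
            old = base.row(t)
            new = [c for j, c in enumerate(var.matrix.row(t)) if j not in inserted]
            assert new == old


class TestBuildVariant:
    def test_empty_plan_identity(self, tiny):
        var = R.build_matrix_variant(tiny, R.RecodingPlan(), "base")
        assert var.matrix == tiny

    def test_merge_plus_all_convergent(self, fixture_suite):
        base = fixture_suite.paper_shaped_matrix
        actions = R.default_feature_actions(
            carapace_char=3, spines_char=17, rays_char=42,
            focal_group="castle_bank", rays_observed=base.observed_states(42),
        )
        plan = R.RecodingPlan(
            merge=("castle_bank1", "castle_bank2", "castle_bank_sp"),
            convergent_features=("carapace", "proboscis_dorsal_spines",
                                 "strengthening_rays"),
            feature_actions=actions,
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", R.MergeConflictWarning)
            var = R.build_matrix_variant(base, plan, "one_terminal_all_convergent",
                                         expected_dims=(56, 131))
        assert (var.matrix.ntax, var.matrix.nchar) == (56, 131)

    def test_dimension_mismatch_names_variant(self, tiny):
        with pytest.raises(ValueError, match="bad_variant"):
            R.build_matrix_variant(tiny, R.RecodingPlan(), "bad_variant",
                                   expected_dims=(99, 3))

    def test_full_analysis_grid_eight_variants(self, fixture_suite):
        """The study grid: two-/one-terminal bases, sensitivity-taxon
        additions, and the four convergence variants."""
        import warnings

        base = fixture_suite.paper_shaped_matrix
        merge = ("castle_bank1", "castle_bank2", "castle_bank_sp")
        actions = R.default_feature_actions(
            carapace_char=3, spines_char=17, rays_char=42,
            focal_group="castle_bank", rays_observed=base.observed_states(42),
        )
        add_pair = [
            R.AddedTaxon("kylinxia", tuple([MISSING] * 129)),
            R.AddedTaxon("parapeytoia", tuple([MISSING] * 130), variant_label="proto",
                         extra_char=R.ExtraCharacter(index=54, default=MISSING)),
        ]
        grid = [
            ("two_terminals", R.RecodingPlan(), (57, 129)),
            ("one_terminal", R.RecodingPlan(merge=merge), (56, 129)),
            ("sensitivity_proto", R.RecodingPlan(add_taxa=add_pair), (59, 130)),
            ("sensitivity_deutero", R.RecodingPlan(add_taxa=add_pair), (59, 130)),
            ("conv_carapace",
             R.RecodingPlan(merge=merge, convergent_features=("carapace",),
                            feature_actions=actions), (56, 130)),
            ("conv_spines",
             R.RecodingPlan(merge=merge,
                            convergent_features=("proboscis_dorsal_spines",),
                            feature_actions=actions), (56, 130)),
            ("conv_rays",
             R.RecodingPlan(merge=merge, convergent_features=("strengthening_rays",),
                            feature_actions=actions), (56, 129)),
            ("conv_all_three",
             R.RecodingPlan(merge=merge,
                            convergent_features=("carapace",
                                                 "proboscis_dorsal_spines",
                                                 "strengthening_rays"),
                            feature_actions=actions), (56, 131)),
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", R.MergeConflictWarning)
            variants = [
                R.build_matrix_variant(base, plan, label, expected_dims=dims)
                for label, plan, dims in grid
            ]
        assert len(variants) == 8
        assert len({v.label for v in variants}) == 8


class TestCellsFromString:
    def test_mixed_string(self):
        cells = R.cells_from_string("01?-{02}(13)")
        assert [c.kind for c in cells] == [
            "observed", "observed", "missing", "inapplicable",
            "polymorphic", "polymorphic",
        ]
        assert cells[4].states == frozenset({0, 2})

    def test_bad_symbol(self):
        with pytest.raises(ValueError):
            R.cells_from_string("0A")
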