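"""Prevalence, lineage cores, overlap partitions, core containment."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from genomedecay.comparative import (core_containment,
                                     core_containment_summary,
                                     core_reaction_set,
                                     global_conserved_core,
                                     lineage_core_model, overlap_partition,
                                     reaction_prevalence)
from genomedecay.fba import maximize_biomass, six_step_analysis
from genomedecay.gapfilling import apply_gapfill
from genomedecay.model import GenomeAnnotation, build_model_from_annotation


def _models_with(universe, role_sets):
    """One model per role set (plus protected transporter roles)."""
    out = []
    for i, roles in enumerate(role_sets):
        ann = GenomeAnnotation(
            f"m{i}", tuple((f"g_m{i}_{r}", r) for r in sorted(roles)))
        out.append(build_model_from_annotation(ann, universe.db))
    return out


class TestPrevalence:
    def test_fraction_of_models_containing_reaction(self, universe):
        role = "role_his_like_1"
        models = _models_with(universe, [{role}, {role}, {role}, set()])
        _, prevalence = reaction_prevalence(models)
        assert prevalence["R_his_like_1"] == Fraction(3, 4)

    def test_gapfilled_occurrences_are_excluded(self, universe):
        models = _models_with(
            universe, [{"role_his_like_1"}, {"role_his_like_1"},
                       set(), set()])
        models[2] = apply_gapfill(models[2], universe.db, ["R_his_like_1"])
        models[3] = apply_gapfill(models[3], universe.db, ["R_his_like_1"])
        _, prevalence = reaction_prevalence(models,
                                            gene_associated_only=True)
        assert prevalence["R_his_like_1"] == Fraction(2, 4)
        matrix, _ = reaction_prevalence(models, gene_associated_only=False)
        assert matrix.values["R_his_like_1"].sum() == 4

    def test_matrix_matches_hand_built_expectation(self, universe):
        models = _models_with(universe,
                              [{"role_his_like_1"}, {"role_trp_like_1"}])
        matrix, _ = reaction_prevalence(models)
        assert matrix.values.loc["m0", "R_his_like_1"] == 1
        assert matrix.values.loc["m0", "R_trp_like_1"] == 0
        assert matrix.values.loc["m1", "R_trp_like_1"] == 1


class TestLineageCore:
    def test_three_of_four_included_two_of_four_excluded(self, universe):
        r = "role_his_like_1"
        s = "role_trp_like_1"
        models = _models_with(
            universe, [{r, s}, {r, s}, {r}, set()])
        core = core_reaction_set(models, threshold=Fraction(3, 4))
        assert "R_his_like_1" in core     # 3/4 >= 75%, boundary inclusive
        assert "R_trp_like_1" not in core  # 2/4 < 75%

    def test_threshold_one_equals_intersection(self, scenario_models):
        models = list(scenario_models.values())[:6]
        core = core_reaction_set(models, threshold=Fraction(1))
        assert core == frozenset.intersection(
            *(m.gene_associated_reaction_ids() for m in models))

    def test_shared_pathway_core_model_is_prototrophic(
            self, universe, scenario, scenario_models):
        # lineage II never loses anything: its core keeps every pathway and
        # the core model needs only the carbon source
        members = [g for g in sorted(scenario.genomes)
                   if scenario.truth[g]["lineage"] == "lineage_II"][:4]
        model, solution = lineage_core_model(
            [scenario_models[g] for g in members], universe.db)
        analysis = six_step_analysis(model)
        assert "aa_his_like_e" not in analysis.minimal_medium.nutrients
        assert analysis.minimal_medium.nutrients == {"carbon_e"}

    def test_core_models_grow_after_gapfilling(self, universe, scenario,
                                               scenario_models):
        for lineage, members in scenario.lineage_members().items():
            model, _ = lineage_core_model(
                [scenario_models[g] for g in members], universe.db,
                lineage_id=lineage)
            fs = maximize_biomass(model,
                                  universe.db.complete_medium())
            assert fs.status == "optimal" and fs.objective_value > 1e-6

    def test_core_contains_never_lost_reactions(self, scenario,
                                                scenario_models, universe):
        # generator truth: reactions present gene-associated in every member
        # must survive the 75% threshold
        for lineage, members in scenario.lineage_members().items():
            models = [scenario_models[g] for g in members]
            never_lost = frozenset.intersection(
                *(m.gene_associated_reaction_ids() for m in models))
            core = core_reaction_set(models)
            assert never_lost <= core


class TestOverlapPartition:
    def test_identical_sets_fill_only_intersection(self):
        out = overlap_partition({"A": {1, 2}, "B": {1, 2}})
        assert out == {"A": 0, "B": 0, "A&B": 2}

    def test_disjoint_sets_fill_only_singletons(self):
        out = overlap_partition({"A": {1}, "B": {2}, "C": {3}})
        assert out["A"] == out["B"] == out["C"] == 1
        assert sum(out.values()) == 3

    def test_known_partition_counts(self):
        out = overlap_partition({"A": {1, 2, 3}, "B": {2, 3, 4},
                                 "C": {3, 4, 5}})
        assert out == {"A": 1, "B": 0, "C": 1, "A&B": 1, "A&C": 0,
                       "B&C": 1, "A&B&C": 1}

    @given(st.lists(st.sets(st.integers(0, 15)), min_size=2, max_size=4))
    def test_region_counts_sum_to_union(self, sets):
        labeled = {f"S{i}": s for i, s in enumerate(sets)}
        out = overlap_partition(labeled)
        assert sum(out.values()) == len(set().union(*sets))


class TestCoreContainment:
    def test_subset_core_gives_one(self):
        assert core_containment({"L": {1, 2}}, {1, 2, 3}) == {"L": 1.0}

    def test_disjoint_core_gives_zero(self):
        assert core_containment({"L": {1, 2}}, {3}) == {"L": 0.0}

    def test_scenario_fractions_match_set_algebra(self, scenario,
                                                  scenario_models):
        cores = {
            lineage: core_reaction_set([scenario_models[g] for g in members])
            for lineage, members in scenario.lineage_members().items()}
        global_core = global_conserved_core(list(scenario_models.values()))
        fractions = core_containment(cores, global_core)
        for lineage, core in cores.items():
            assert fractions[lineage] == pytest.approx(
                len(core & global_core) / len(core))
        summary = core_containment_summary(cores, global_core)
        assert 0.0 <= summary["pooled"] <= 1.0
        assert summary["mean"] == pytest.approx(
            np.mean(list(fractions.values())))
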