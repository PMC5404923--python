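"""Six-step flux-balance procedure against brute-force enumeration oracles."""

import numpy as np
import pytest

from genomedecay import oracles
from genomedecay.fba import (AuxotrophicError, ReactionClass,
                             classify_reactions, complete_medium,
                             find_minimal_media, flux_variability,
                             maximize_biomass, parsimonious_flux,
                             six_step_analysis)
from genomedecay.model import CYTOSOL, EXTRACELLULAR, Medium
from genomedecay.simulate import random_toy_network

from conftest import make_model, nutrient_rxns


def residual(model, fluxes):
    S, mets, rxns = model.stoichiometric_matrix()
    v = np.array([fluxes[r] for r in rxns])
    return float(np.max(np.abs(S @ v)))


class TestMaximizeBiomass:
    def test_uptake_limited_chain_reaches_cap(self, chain_model):
        fs = maximize_biomass(chain_model, complete_medium(chain_model))
        assert fs.status == "optimal"
        assert fs.objective_value == pytest.approx(10.0, abs=1e-7)
        assert residual(chain_model, fs.fluxes) <= 1e-7

    def test_empty_medium_gives_zero_growth(self, chain_model):
        fs = maximize_biomass(chain_model, Medium(nutrients=frozenset()))
        assert fs.objective_value == pytest.approx(0.0, abs=1e-7)

    def test_branched_network_matches_vertex_enumeration(
            self, branched_model):
        medium = complete_medium(branched_model)
        fs = maximize_biomass(branched_model, medium)
        vmax = oracles.max_biomass_vertices(branched_model, medium)
        assert fs.objective_value == pytest.approx(vmax, abs=1e-6)


class TestMinimalMedia:
    def test_two_required_precursors_need_both_nutrients(
            self, two_precursor_model):
        pred = find_minimal_media(two_precursor_model, growth_floor=1.0)
        assert pred.medium.nutrients == {"A_e", "B_e"}
        assert pred.medium.nutrients == oracles.minimal_media_bruteforce(
            two_precursor_model, 1.0)
        assert pred.achieved_biomass >= 1.0

    def test_substitutable_routes_pick_lexicographic_smallest(
            self, branched_model):
        # exhaustive search confirms two singleton optima {A_e} and {B_e};
        # the deterministic tie-break must pick {A_e}
        pred = find_minimal_media(branched_model, growth_floor=1.0)
        assert pred.medium.nutrients == {"A_e"}
        assert pred.medium.nutrients == oracles.minimal_media_bruteforce(
            branched_model, 1.0)

    def test_self_sufficient_model_needs_no_nutrients(self):
        model = make_model(
            "selfsuff",
            {"A_e": EXTRACELLULAR, "P_c": CYTOSOL},
            nutrient_rxns("A")[:1] + [
                ("GEN", {"P_c": 1}, {}),
                ("BIO", {"P_c": -1}, {}),
            ])
        pred = find_minimal_media(model, growth_floor=1.0)
        assert pred.medium.nutrients == frozenset()

    def test_nongrowing_model_raises_auxotrophic_error(self, chain_model):
        broken = chain_model.copy()
        del broken.reactions["R1"]
        with pytest.raises(AuxotrophicError, match="complete medium"):
            find_minimal_media(broken, growth_floor=1.0)


class TestFvaAndClassification:
    def test_essential_chain_reaction_pinned_at_cap(self, chain_model):
        medium = complete_medium(chain_model)
        fva = flux_variability(chain_model, medium,
                               {"BIO": (10.0 - 1e-9, np.inf)})
        assert fva["R1"] == pytest.approx((10.0, 10.0), abs=1e-6)

    def test_blocked_reaction_under_minimal_medium_is_zero(
            self, branched_model):
        medium = Medium(nutrients=frozenset({"A_e"}))
        fva = flux_variability(branched_model, medium)
        assert fva["R1b"] == pytest.approx((0.0, 0.0), abs=1e-9)
        assert fva["T_B"] == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_substitutable_duplicates_span_zero_to_demand(
            self, branched_model):
        medium = complete_medium(branched_model)
        fva = flux_variability(branched_model, medium,
                               {"BIO": (10.0, np.inf)})
        oracle = oracles.fva_vertices(branched_model, medium,
                                      {"BIO": (10.0, np.inf)})
        for rid in ("R1a", "R1b"):
            assert fva[rid][0] == pytest.approx(oracle[rid][0], abs=1e-6)
            assert fva[rid][1] == pytest.approx(oracle[rid][1], abs=1e-6)
            assert fva[rid][0] == pytest.approx(0.0, abs=1e-6)
            assert fva[rid][1] == pytest.approx(10.0, abs=1e-6)

    @pytest.mark.parametrize("rng,expected", [
        ((10.0, 10.0), ReactionClass.ESSENTIAL),
        ((-10.0, -10.0), ReactionClass.ESSENTIAL),
        ((0.0, 0.0), ReactionClass.NONFUNCTIONAL),
        ((0.0, 7.0), ReactionClass.FUNCTIONAL),
        ((-3.0, 5.0), ReactionClass.FUNCTIONAL),
    ])
    def test_classification_rule(self, rng, expected):
        assert classify_reactions({"r": rng})["r"] is expected


class TestParsimoniousFlux:
    def test_futile_loop_carries_no_flux(self):
        model = make_model(
            "loopy",
            {"A_e": EXTRACELLULAR, "A_c": CYTOSOL, "P_c": CYTOSOL,
             "X_c": CYTOSOL},
            nutrient_rxns("A") + [
                ("R1", {"A_c": -1, "P_c": 1}, {}),
                ("L1", {"P_c": -1, "X_c": 1}, {}),
                ("L2", {"X_c": -1, "P_c": 1}, {}),
                ("BIO", {"P_c": -1}, {}),
            ])
        fs = parsimonious_flux(model, complete_medium(model))
        assert fs.fluxes["L1"] == pytest.approx(0.0, abs=1e-7)
        assert fs.fluxes["L2"] == pytest.approx(0.0, abs=1e-7)

    def test_linear_chain_carries_throughput(self, chain_model):
        fs = parsimonious_flux(chain_model, complete_medium(chain_model))
        assert fs.fluxes["R1"] == pytest.approx(10.0, abs=1e-6)
        assert fs.objective_value == pytest.approx(10.0, abs=1e-6)

    def test_total_flux_matches_orthant_enumeration(self, branched_model):
        medium = complete_medium(branched_model)
        vmax = maximize_biomass(branched_model, medium).objective_value
        fs = parsimonious_flux(branched_model, medium, vmax)
        total = sum(abs(v) for v in fs.fluxes.values())
        assert total == pytest.approx(
            oracles.pfba_bruteforce(branched_model, medium, vmax), abs=1e-5)


class TestSixStep:
    def test_composition_is_internally_consistent(self, branched_model):
        analysis = six_step_analysis(branched_model)
        assert analysis.grows_on_complete
        assert analysis.parsimonious.objective_value == pytest.approx(
            analysis.max_biomass_minimal, abs=1e-6)
        assert set(analysis.classes) == set(branched_model.reactions)
        # every minimal-medium nutrient has an essential exchange reaction
        for nutrient in analysis.minimal_medium.nutrients:
            assert analysis.classes[f"EX_{nutrient}"] is \
                ReactionClass.ESSENTIAL

    def test_missing_pathway_forces_amino_acid_into_medium(
            self, scenario, scenario_models):
        broken = [g for g in sorted(scenario.genomes)
                  if "trp_like" in scenario.truth[g]["lost_pathways"]]
        g = broken[0]
        analysis = six_step_analysis(scenario_models[g])
        assert "aa_trp_like_e" in analysis.minimal_medium.nutrients

    def test_complete_pathway_keeps_amino_acid_out_of_medium(
            self, scenario, scenario_models):
        intact = [g for g in sorted(scenario.genomes)
                  if not scenario.truth[g]["lost_pathways"]]
        analysis = six_step_analysis(scenario_models[intact[0]])
        assert analysis.minimal_medium.nutrients == {"carbon_e"}


class TestProperties:
    @pytest.mark.parametrize("seed", range(8))
    def test_enlarging_medium_never_decreases_biomass(self, seed):
        model = random_toy_network(seed)
        nutrients = sorted(model.exchangeable_metabolites)
        prev = -1.0
        for k in range(len(nutrients) + 1):
            medium = Medium(nutrients=frozenset(nutrients[:k]))
            v = maximize_biomass(model, medium).objective_value
            assert v >= prev - 1e-7
            prev = v

    @pytest.mark.parametrize("seed", range(8))
    def test_feasibility_residuals_within_tolerance(self, seed):
        model = random_toy_network(seed)
        fs = maximize_biomass(model, complete_medium(model))
        assert residual(model, fs.fluxes) <= 1e-7
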