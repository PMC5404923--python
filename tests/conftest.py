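"""Shared fixtures: hand-built flux networks and the standard decay scenario."""

from __future__ import annotations

from fractions import Fraction

import pytest
from hypothesis import HealthCheck, settings

from genomedecay.model import (CYTOSOL, EXTRACELLULAR, Metabolite, Reaction,
                               StoichiometricModel)
from genomedecay.simulate import default_scenario, generate_universe

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def make_model(genome_id, mets, rxns, biomass="BIO"):
    """mets: {id: compartment}; rxns: list of (id, stoich, kwargs)."""
    metabolites = [Metabolite(id=m, name=m, compartment=c)
                   for m, c in mets.items()]
    reactions = []
    for rid, stoich, kw in rxns:
        kw = dict(kw)
        kw.setdefault("lower_bound", 0.0)
        kw.setdefault("upper_bound", 1000.0)
        reactions.append(Reaction(
            id=rid, stoichiometry={m: Fraction(c) for m, c in stoich.items()},
            **kw))
    return StoichiometricModel.from_components(
        genome_id, metabolites, reactions, biomass)


def nutrient_rxns(label, gene=True):
    """Exchange + transporter pair for one extracellular nutrient."""
    gpr = ((f"g_T_{label}",),) if gene else ()
    return [
        (f"EX_{label}_e", {f"{label}_e": -1},
         dict(lower_bound=-10.0, is_exchange=True)),
        (f"T_{label}", {f"{label}_e": -1, f"{label}_c": 1},
         dict(gene_association=gpr)),
    ]


@pytest.fixture
def chain_model():
    """EX_A -> T_A -> R1(A_c -> P_c) -> biomass; uptake cap 10."""
    return make_model(
        "chain",
        {"A_e": EXTRACELLULAR, "A_c": CYTOSOL, "P_c": CYTOSOL},
        nutrient_rxns("A") + [
            ("R1", {"A_c": -1, "P_c": 1},
             dict(gene_association=(("g_R1",),))),
            ("BIO", {"P_c": -1}, {}),
        ])


@pytest.fixture
def branched_model():
    """Two substitutable precursor routes (A or B) into biomass."""
    return make_model(
        "branched",
        {"A_e": EXTRACELLULAR, "B_e": EXTRACELLULAR,
         "A_c": CYTOSOL, "B_c": CYTOSOL, "P_c": CYTOSOL},
        nutrient_rxns("A") + nutrient_rxns("B") + [
            ("R1a", {"A_c": -1, "P_c": 1},
             dict(gene_association=(("g_R1a",),))),
            ("R1b", {"B_c": -1, "P_c": 1},
             dict(gene_association=(("g_R1b",),))),
            ("BIO", {"P_c": -1}, {}),
        ])


@pytest.fixture
def two_precursor_model():
    """Biomass jointly requires P1 (only from A) and P2 (only from B)."""
    return make_model(
        "twoprec",
        {"A_e": EXTRACELLULAR, "B_e": EXTRACELLULAR,
         "A_c": CYTOSOL, "B_c": CYTOSOL, "P1_c": CYTOSOL, "P2_c": CYTOSOL},
        nutrient_rxns("A") + nutrient_rxns("B") + [
            ("R1", {"A_c": -1, "P1_c": 1},
             dict(gene_association=(("g_R1",),))),
            ("R2", {"B_c": -1, "P2_c": 1},
             dict(gene_association=(("g_R2",),))),
            ("BIO", {"P1_c": -1, "P2_c": -1}, {}),
        ])


@pytest.fixture(scope="session")
def universe():
    return generate_universe()


@pytest.fixture(scope="session")
def scenario():
    """Standard 20-genome, 4-lineage decay scenario (no discordances)."""
    return default_scenario(seed=11)


@pytest.fixture(scope="session")
def scenario_models(scenario):
    return scenario.build_models()
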