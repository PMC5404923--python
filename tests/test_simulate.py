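"""Generator ground truth: universe structure, decay dynamics, codon
evolution bookkeeping, fixture determinism."""

import hashlib
import math
from pathlib import Path

import numpy as np
import pytest

from genomedecay.fba import maximize_biomass
from genomedecay.model import Medium, build_model_from_annotation
from genomedecay.occurrence import Phylogeny
from genomedecay.simulate import (branch_loss_probability,
                                  default_environments, default_scenario,
                                  default_tree, emit_fixtures,
                                  generate_universe,
                                  simulate_codon_evolution, simulate_decay)


def _dir_digest(path: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(path.rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


class TestUniverse:
    def test_convergent_pathways_have_ten_and_seven_roles(self, universe):
        assert len(universe.pathway("his_like").expected_roles) == 10
        assert len(universe.pathway("trp_like").expected_roles) == 7
        assert universe.focal_role in \
            universe.pathway("his_like").expected_roles
        assert universe.focal_role in \
            universe.pathway("trp_like").expected_roles

    def test_focal_role_maps_to_two_reactions(self, universe):
        assert len(universe.db.role_map[universe.focal_role]) == 2

    def test_role_map_covers_every_chain_reaction(self, universe):
        mapped = set().union(*universe.db.role_map.values())
        chains = {r for r in universe.db.reactions
                  if r.startswith(("R_", "T_"))}
        assert chains <= mapped

    def test_minimal_two_pathway_universe_grows_when_complete(self):
        small = generate_universe(n_pathways=2, pathway_lengths=(10, 7))
        roles = set(small.db.role_map)
        from genomedecay.model import GenomeAnnotation
        ann = GenomeAnnotation("full", tuple(
            (f"g_{r}", r) for r in sorted(roles)))
        model = build_model_from_annotation(ann, small.db)
        fs = maximize_biomass(model, small.db.complete_medium())
        assert fs.status == "optimal" and fs.objective_value > 1.0

    def test_database_validates(self, universe):
        assert universe.db.validate() == []


class TestDecay:
    def test_zero_loss_rate_keeps_all_genomes_identical_to_root(self):
        universe = generate_universe()
        _, tree = default_tree(3)
        scenario = simulate_decay(universe, tree,
                                  default_environments(universe),
                                  loss_rate=0.0, seed=4)
        full_roles = scenario.genomes["g01"].roles
        for ann in scenario.genomes.values():
            assert ann.roles == full_roles
        assert all(not t["lost_pathways"]
                   for t in scenario.truth.values())

    def test_every_genome_is_viable_in_its_environment(self, scenario):
        for g, ann in scenario.genomes.items():
            model = build_model_from_annotation(ann, scenario.universe.db)
            fs = maximize_biomass(model, scenario.growth_medium(g))
            assert fs.status == "optimal" and fs.objective_value > 1e-6, g

    def test_protected_lineage_never_loses_pathways(self, scenario):
        for g, t in scenario.truth.items():
            if t["lineage"] == "lineage_II":
                assert t["lost_pathways"] == []

    def test_truth_consistent_with_annotations(self, scenario):
        for g, t in scenario.truth.items():
            roles = scenario.genomes[g].roles
            assert t["focal_present"] == \
                (scenario.universe.focal_role in roles)
            assert frozenset(t["lost_pathways"]) == \
                scenario.universe.broken_pathways(roles)

    def test_focal_gene_follows_pathway_retention(self, scenario):
        # coevolution by construction: focal present <=> >=1 dependent
        # pathway retained (no discordances planted here)
        for t in scenario.truth.values():
            dependent_retained = bool(
                {"his_like", "trp_like"} & set(t["retained_pathways"]))
            assert t["focal_present"] == dependent_retained

    def test_supplied_lineage_shows_partial_trp_decay_profile(self):
        # a lineage fed the trp-like product decays trp below the 90%
        # completeness call while his stays complete
        scenario = default_scenario(seed=11)
        lineage_i = [g for g, t in scenario.truth.items()
                     if t["lineage"] == "lineage_I"]
        assert lineage_i
        for g in lineage_i:
            t = scenario.truth[g]
            assert "trp_like" not in t["retained_pathways"]
            assert "his_like" in t["retained_pathways"]

    def test_branch_loss_frequency_matches_closed_form(self):
        universe = generate_universe()
        newick = "(ga:0.5,gb:0.5)lineage_IV:0.0;"
        env = {"lineage_IV": frozenset(
            universe.nutrient_pathway_map)}  # everything supplied
        lost = 0
        total = 0
        target_roles = universe.chain_roles("his_like")
        for seed in range(120):
            tree = Phylogeny.from_newick(newick)
            sc = simulate_decay(universe, tree, env, loss_rate=1.0,
                                seed=seed, validate_viability=False)
            roles = sc.genomes["ga"].roles
            lost += len(target_roles - roles)
            total += len(target_roles)
        expected = branch_loss_probability(1.0, 0.5)
        assert lost / total == pytest.approx(expected, abs=0.03)


class TestCodonEvolution:
    def test_zero_mutation_rate_keeps_sequences_identical(self):
        _, tree = default_tree(3)
        sim = simulate_codon_evolution(tree, root_length=60,
                                       mutation_rate=0.0, seed=1)
        seqs = set(sim.alignment.sequences.values())
        assert seqs == {sim.root_sequence}

    def test_alignment_has_no_internal_stops_and_equal_lengths(self):
        _, tree = default_tree(3)
        sim = simulate_codon_evolution(tree, root_length=100,
                                       mutation_rate=1.0, seed=2)
        lengths = {len(s) for s in sim.alignment.sequences.values()}
        assert lengths == {300}

    def test_fixation_bookkeeping_recovers_omega(self):
        # nonsynonymous proposals fix with probability omega
        _, tree = default_tree(5)
        omega = 0.25
        fixed = proposed = 0
        for seed in range(30):
            sim = simulate_codon_evolution(
                tree, root_length=200,
                clade_omegas={lab: omega for lab in
                              ("lineage_I", "lineage_II", "lineage_III",
                               "lineage_IV")},
                mutation_rate=1.0, seed=seed, default_omega=omega)
            for counts in sim.counts.values():
                fixed += counts["nonsyn_fixed"]
                proposed += counts["nonsyn_proposed"]
        assert fixed / proposed == pytest.approx(omega, abs=0.02)

    def test_synonymous_proposals_always_fix(self):
        _, tree = default_tree(3)
        sim = simulate_codon_evolution(tree, root_length=150,
                                       mutation_rate=1.0, seed=9)
        for counts in sim.counts.values():
            assert counts["syn_fixed"] == counts["syn_proposed"]


class TestFixtures:
    def test_same_seed_emits_byte_identical_trees(self, tmp_path):
        for sub in ("a", "b"):
            scenario = default_scenario(seed=7, n_per_lineage=3)
            sim = simulate_codon_evolution(
                scenario.phylogeny, root_length=60,
                clade_omegas=scenario.clade_omegas, seed=7)
            emit_fixtures(scenario, tmp_path / sub, sim)
        assert _dir_digest(tmp_path / "a") == _dir_digest(tmp_path / "b")

    def test_manifest_matches_written_inventory(self, tmp_path):
        scenario = default_scenario(seed=7, n_per_lineage=3)
        manifest = emit_fixtures(scenario, tmp_path / "fx")
        written = sorted(p.name for p in (tmp_path / "fx").iterdir())
        assert manifest == written

    def test_fixtures_round_trip_to_equal_scenario_inputs(self, tmp_path):
        from genomedecay.io import read_annotations, read_database
        from genomedecay.simulate import load_pathways
        scenario = default_scenario(seed=7, n_per_lineage=3)
        out = tmp_path / "fx"
        emit_fixtures(scenario, out)
        anns = read_annotations(out / "annotations.tsv")
        assert anns == scenario.genomes
        db = read_database(out / "universe.json")
        assert set(db.reactions) == set(scenario.universe.db.reactions)
        pathways, nutrient_map, focal = load_pathways(out / "pathways.json")
        assert pathways == scenario.universe.pathways
        assert nutrient_map == scenario.universe.nutrient_pathway_map
        assert focal == scenario.universe.focal_role
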