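"""Ground-truth generators: a toy universal biochemistry, phylogeny-
conditioned genome decay, and codon evolution under clade-specific omega.

The universe consists of linear amino-acid biosynthesis chains that all
start from a single transportable carbon source and end in biomass
precursors.  Two designated pathways (histidine-like, 10 roles, and
tryptophan-like, 7 roles) converge on one bifunctional isomerase role, and
every amino-acid end product is itself transportable (salvage), so a
lineage supplied with an amino acid can afford to lose the pathway that
makes it.  Because biosynthesis shares the carbon source while salvage
costs one extra nutrient per pathway, a genome's minimal medium is exactly
the carbon source plus the end product of every broken pathway — which is
what lets auxotrophy predictions be scored against generator truth.

Gene loss is irreversible along branches, with per-gene branch-loss
probability 1 - exp(-loss_rate * branch_length); pathways whose product
the lineage environment does not supply are protected, and the
bifunctional focal gene is deleted only once both dependent pathways are
lost.  Codon evolution proposes point mutations at a Poisson rate and
accepts synonymous changes always, nonsynonymous changes with the
governing clade's omega (no indels).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .dnds import CODON_TO_AA, CodonAlignment, SENSE_CODONS, STOP_CODONS
from .fba import maximize_biomass
from .io import (annotations_to_tsv, database_to_json, write_annotations,
                 write_database)
from .model import (CYTOSOL, EXTRACELLULAR, GenomeAnnotation, Medium,
                    Metabolite, Reaction, StoichiometricModel,
                    UniversalDatabase, build_model_from_annotation)
from .occurrence import PathwayDefinition, Phylogeny
from .orthology import write_fasta

FOCAL_ROLE = "role_priA"
CARBON_EXT = "carbon_e"
FLUX_MAX = 1000.0

#: step index (1-based) of the bifunctional reaction in each designated chain
_FOCAL_STEP = {"his_like": 5, "trp_like": 3}


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# universe generation


@dataclass
class UniverseBundle:
    """A universal database plus the pathway bookkeeping built with it."""

    db: UniversalDatabase
    pathways: list[PathwayDefinition]
    #: amino-acid nutrient id -> pathway name (for auxotrophy scoring)
    nutrient_pathway_map: dict[str, str]
    focal_role: str
    #: roles every genome always carries (transporters, core metabolism)
    protected_roles: frozenset[str]
    #: per pathway, the role alternatives able to catalyze each chain step
    #: (an analogous isoenzyme makes a step's set larger than one)
    step_roles: dict[str, list[frozenset[str]]] = field(default_factory=dict)

    def broken_pathways(self, roles: frozenset[str] | set[str]
                        ) -> frozenset[str]:
        """Pathways with at least one chain step no annotated role covers."""
        return frozenset(
            name for name, steps in self.step_roles.items()
            if any(not (alternatives & roles) for alternatives in steps))

    @property
    def pathway_names(self) -> list[str]:
        return [p.name for p in self.pathways]

    def pathway(self, name: str) -> PathwayDefinition:
        for p in self.pathways:
            if p.name == name:
                return p
        raise KeyError(name)

    def chain_roles(self, name: str) -> frozenset[str]:
        """Biosynthetic roles of a pathway, focal role excluded."""
        return self.pathway(name).expected_roles - {self.focal_role}

    def aa_nutrient(self, name: str) -> str:
        for nutrient, pw in self.nutrient_pathway_map.items():
            if pw == name:
                return nutrient
        raise KeyError(name)


def _rxn(rid, stoich, role=None, lb=0.0, ub=FLUX_MAX, exchange=False):
    return Reaction(id=rid, stoichiometry={m: Fraction(c) for m, c in
                                           stoich.items()},
                    lower_bound=lb, upper_bound=ub, is_exchange=exchange), role


def generate_universe(
    n_pathways: int = 4,
    pathway_lengths: tuple[int, ...] = (10, 7, 5, 4),
    seed: int = 0,
) -> UniverseBundle:
    """Build the toy universal biochemistry (deterministic per arguments).

    The first two pathways are the designated convergent pair (lengths must
    be the classic 10 and 7 so their completeness bookkeeping mirrors the
    histidine/tryptophan gene counts); additional pathways are independent
    chains.  All chains run from the shared cytosolic carbon pool to an
    amino-acid end product consumed by biomass.
    """
    if n_pathways < 2:
        raise ValueError("need at least the two convergent pathways")
    if len(pathway_lengths) != n_pathways:
        raise ValueError("one length per pathway required")
    if any(l < 2 for l in pathway_lengths):
        raise ValueError("pathway lengths must be >= 2")
    names = ["his_like", "trp_like"] + [
        f"aux_p{i}" for i in range(3, n_pathways + 1)]

    mets: dict[str, Metabolite] = {}
    reactions: dict[str, Reaction] = {}
    role_map: dict[str, set[str]] = {}
    protected: set[str] = set()

    def add_met(mid, compartment):
        mets[mid] = Metabolite(id=mid, name=mid, compartment=compartment)

    def add(rid, stoich, role, protect=False):
        rxn, _ = _rxn(rid, stoich)
        reactions[rid] = rxn
        if role is not None:
            role_map.setdefault(role, set()).add(rid)
            if protect:
                protected.add(role)

    add_met(CARBON_EXT, EXTRACELLULAR)
    add_met("carbon_c", CYTOSOL)
    add_met("central_c", CYTOSOL)
    add("T_carbon", {CARBON_EXT: -1, "carbon_c": 1}, "role_T_carbon",
        protect=True)
    add("R_central", {"carbon_c": -1, "central_c": 1}, "role_central",
        protect=True)

    pathways: list[PathwayDefinition] = []
    step_roles: dict[str, list[frozenset[str]]] = {}
    nutrient_map: dict[str, str] = {}
    transportable = {CARBON_EXT}
    biomass_needs = {"central_c": -1}

    for name, length in zip(names, pathway_lengths):
        aa_c, aa_e = f"aa_{name}_c", f"aa_{name}_e"
        add_met(aa_c, CYTOSOL)
        add_met(aa_e, EXTRACELLULAR)
        focal_step = _FOCAL_STEP.get(name)
        roles = set()
        steps: list[frozenset[str]] = []
        prev = "central_c"
        for step in range(1, length + 1):
            product = aa_c if step == length else f"m_{name}_{step}_c"
            if product != aa_c:
                add_met(product, CYTOSOL)
            role = (FOCAL_ROLE if step == focal_step
                    else f"role_{name}_{step}")
            add(f"R_{name}_{step}", {prev: -1, product: 1}, role)
            roles.add(role)
            step_alternatives = {role}
            if name == "aux_p3" and step == 2:
                # an analogous (non-homologous) isoenzyme covering the same
                # transformation; protected, so this step never breaks
                analog_role = f"role_analog_{name}"
                add(f"R_{name}_{step}b", {prev: -1, product: 1}, analog_role,
                    protect=True)
                step_alternatives.add(analog_role)
            steps.append(frozenset(step_alternatives))
            prev = product
        step_roles[name] = steps
        add(f"T_aa_{name}", {aa_e: -1, aa_c: 1}, f"role_T_aa_{name}",
            protect=True)
        transportable.add(aa_e)
        nutrient_map[aa_e] = name
        biomass_needs[aa_c] = -1
        shared = frozenset({FOCAL_ROLE}) if focal_step else frozenset()
        pathways.append(PathwayDefinition(
            name=name, expected_roles=frozenset(roles),
            completeness_threshold=Fraction(9, 10), shared_roles=shared))

    reactions["biomass"], _ = _rxn("biomass", biomass_needs)

    db = UniversalDatabase(
        metabolites=mets,
        reactions=reactions,
        role_map={r: frozenset(v) for r, v in role_map.items()},
        transportable=frozenset(transportable),
        biomass_reaction_id="biomass",
    )
    problems = db.validate()
    if problems:  # pragma: no cover - construction is deterministic
        raise SimulationError("; ".join(problems))
    return UniverseBundle(
        db=db, pathways=pathways, nutrient_pathway_map=nutrient_map,
        focal_role=FOCAL_ROLE, protected_roles=frozenset(protected),
        step_roles=step_roles)


# ---------------------------------------------------------------------------
# decay simulation


@dataclass
class DecayScenario:
    universe: UniverseBundle
    phylogeny: Phylogeny
    newick: str
    environments: dict[str, frozenset[str]]
    genomes: dict[str, GenomeAnnotation]
    truth: dict[str, dict]
    clade_omegas: dict[str, float]
    seed: int
    loss_rate: float
    n_discordant: int

    def growth_medium(self, genome_id: str,
                      uptake_limit: float = 10.0) -> Medium:
        lineage = self.truth[genome_id]["lineage"]
        return Medium(
            nutrients=self.environments[lineage] | {CARBON_EXT},
            uptake_limit=uptake_limit)

    def build_models(self, uptake_limit: float = 10.0
                     ) -> dict[str, StoichiometricModel]:
        return {
            g: build_model_from_annotation(ann, self.universe.db,
                                           uptake_limit=uptake_limit)
            for g, ann in sorted(self.genomes.items())
        }

    def lineage_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {l: [] for l in self.environments}
        for g in sorted(self.genomes):
            out[self.truth[g]["lineage"]].append(g)
        return out


def branch_loss_probability(loss_rate: float, branch_length: float) -> float:
    """Closed-form per-gene loss probability along one branch."""
    return 1.0 - math.exp(-loss_rate * branch_length)


def _annotation_for(genome_id: str, roles: set[str]) -> GenomeAnnotation:
    genes = tuple((f"g_{genome_id}_{role}", role) for role in sorted(roles))
    return GenomeAnnotation(genome_id=genome_id, genes=genes)


def simulate_decay(
    universe: UniverseBundle,
    phylogeny: Phylogeny,
    environments: dict[str, frozenset[str]] | dict[str, set[str]],
    loss_rate: float = 2.0,
    seed: int = 0,
    n_discordant: int = 0,
    clade_omegas: dict[str, float] | None = None,
    newick: str | None = None,
    validate_viability: bool = True,
) -> DecayScenario:
    """Progressive, irreversible gene loss along a lineage-labeled tree.

    ``environments`` maps clade labels to the amino-acid nutrients each
    lineage's habitat supplies; only pathways whose product is supplied may
    decay, and only along branches lying entirely within one labeled clade.
    Truth records, per genome: broken ("lost") pathways (>= 1 biosynthetic
    gene deleted), retained pathways (role completeness >= threshold),
    focal-gene presence and any planted discordance.
    """
    rng = np.random.default_rng(seed)
    environments = {l: frozenset(v) for l, v in environments.items()}
    for lineage in environments:
        phylogeny.clade_leaves(lineage)  # raises on unknown clade
    leaf_lineage: dict[str, str] = {}
    for lineage, leaves in sorted(phylogeny.clades.items()):
        if lineage in environments:
            for leaf in leaves:
                leaf_lineage[leaf] = lineage
    all_leaves = set(phylogeny.leaf_order)
    unassigned = all_leaves - set(leaf_lineage)
    if unassigned:
        raise SimulationError(
            f"leaves not covered by any environment lineage: "
            f"{sorted(unassigned)}")

    deletable_by_lineage = {
        lineage: frozenset(
            universe.nutrient_pathway_map[n] for n in nutrients
            if n in universe.nutrient_pathway_map)
        for lineage, nutrients in environments.items()
    }
    all_chain_roles = set()
    for p in universe.pathways:
        all_chain_roles |= (p.expected_roles - {universe.focal_role})

    def branch_lineage(node) -> str | None:
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        for lineage in sorted(environments):
            if leaves <= phylogeny.clades[lineage]:
                return lineage
        return None

    # preorder walk; per-branch deletions in sorted-role order for
    # reproducibility
    root = phylogeny.tree.seed_node
    retained_at: dict[int, set[str]] = {id(root): set(all_chain_roles)}
    leaf_roles: dict[str, set[str]] = {}
    for node in phylogeny.tree.preorder_node_iter():
        if node is root:
            continue
        roles = set(retained_at[id(node.parent_node)])
        lineage = branch_lineage(node)
        if lineage is not None and node.edge.length:
            p_loss = branch_loss_probability(loss_rate, node.edge.length)
            deletable_roles = set()
            for pw in sorted(deletable_by_lineage[lineage]):
                deletable_roles |= universe.chain_roles(pw)
            for role in sorted(roles & deletable_roles):
                if rng.random() < p_loss:
                    roles.discard(role)
        retained_at[id(node)] = roles
        if node.is_leaf():
            leaf_roles[node.taxon.label] = roles

    focal_pathways = [p for p in universe.pathways
                      if universe.focal_role in p.expected_roles]

    genomes: dict[str, GenomeAnnotation] = {}
    truth: dict[str, dict] = {}
    for leaf in sorted(leaf_roles):
        roles = leaf_roles[leaf]
        # completeness counting the focal role as present, to decide whether
        # the focal gene survives
        def completeness(pw: PathwayDefinition, with_focal: bool) -> Fraction:
            present = roles & pw.expected_roles
            if with_focal and universe.focal_role in pw.expected_roles:
                present = present | {universe.focal_role}
            return Fraction(len(present), len(pw.expected_roles))

        retained_with_focal = {
            p.name for p in focal_pathways
            if completeness(p, True) >= p.completeness_threshold}
        focal_present = bool(retained_with_focal)

        final_roles = set(roles) | set(universe.protected_roles)
        if focal_present:
            final_roles.add(universe.focal_role)
        retained = set()
        for p in universe.pathways:
            frac = Fraction(len(final_roles & p.expected_roles),
                            len(p.expected_roles))
            if frac >= p.completeness_threshold:
                retained.add(p.name)
        lost = universe.broken_pathways(frozenset(final_roles))
        genomes[leaf] = _annotation_for(leaf, final_roles)
        truth[leaf] = {
            "lineage": leaf_lineage[leaf],
            "environment": sorted(environments[leaf_lineage[leaf]]),
            "lost_pathways": sorted(lost),
            "retained_pathways": sorted(retained),
            "focal_present": focal_present,
            "discordant": False,
        }

    if n_discordant:
        _plant_discordances(universe, genomes, truth, n_discordant)

    scenario = DecayScenario(
        universe=universe, phylogeny=phylogeny,
        newick=newick or phylogeny.tree.as_string(schema="newick").strip(),
        environments=environments, genomes=genomes, truth=truth,
        clade_omegas=dict(clade_omegas or {}), seed=seed,
        loss_rate=loss_rate, n_discordant=n_discordant)
    if validate_viability:
        _validate_viability(scenario)
    return scenario


def _plant_discordances(universe, genomes, truth, k) -> None:
    """Re-add the focal gene to genomes whose dependent pathways are both
    decayed far enough that the addition cannot re-complete either pathway
    (adding a gene never breaks model viability)."""
    focal_pws = [p for p in universe.pathways
                 if universe.focal_role in p.expected_roles]
    eligible = []
    for g in sorted(genomes):
        if truth[g]["focal_present"]:
            continue
        roles = genomes[g].roles
        ok = True
        for p in focal_pws:
            present = len(roles & p.expected_roles)
            after = Fraction(present + 1, len(p.expected_roles))
            if after >= p.completeness_threshold:
                ok = False
        if ok:
            eligible.append(g)
    if len(eligible) < k:
        raise SimulationError(
            f"only {len(eligible)} genomes eligible for discordance "
            f"planting, need {k}")
    for g in eligible[:k]:
        roles = set(genomes[g].roles) | {universe.focal_role}
        genomes[g] = _annotation_for(g, roles)
        truth[g]["focal_present"] = True
        truth[g]["discordant"] = True


def _validate_viability(scenario: DecayScenario,
                        uptake_limit: float = 10.0) -> None:
    for g, ann in sorted(scenario.genomes.items()):
        model = build_model_from_annotation(ann, scenario.universe.db,
                                            uptake_limit=uptake_limit)
        fs = maximize_biomass(model, scenario.growth_medium(g, uptake_limit))
        if fs.status != "optimal" or fs.objective_value <= 1e-6:
            raise SimulationError(
                f"nonviable genome {g!r} in its environment "
                f"(biomass {fs.objective_value!r})")


# ---------------------------------------------------------------------------
# default study-style scenario


def default_tree(n_per_lineage: int = 5) -> tuple[str, Phylogeny]:
    """Four lineage clades mirroring the study's I-IV split; lineages III
    and IV are sisters.  Leaf-to-clade-root path length is 1.1."""
    lineages = ["lineage_I", "lineage_II", "lineage_III", "lineage_IV"]
    leaves = iter(f"g{i:02d}" for i in range(1, 4 * n_per_lineage + 1))
    clades = []
    def group(ids: list[str]) -> str:
        if len(ids) == 1:
            return f"{ids[0]}:0.6"
        inner = ",".join(f"{g}:0.3" for g in ids)
        return f"({inner}):0.3"

    for lab in lineages:
        ids = [next(leaves) for _ in range(n_per_lineage)]
        half = max(1, len(ids) // 2)
        clades.append(f"({group(ids[:half])},{group(ids[half:])}){lab}:0.5")
    newick = (f"(({clades[0]},{clades[1]}):0.2,"
              f"({clades[2]},{clades[3]}):0.2);")
    return newick, Phylogeny.from_newick(newick)


#: default per-lineage omegas mirror the printed selection regimes: strong
#: purifying selection in the intact lineage, relaxed in the decaying ones
DEFAULT_CLADE_OMEGAS = {
    "lineage_II": 0.0636,
    "lineage_I": 0.0901,
    "lineage_III": 0.1459,
    "lineage_IV": 0.1459,
}


def default_environments(universe: UniverseBundle) -> dict[str, frozenset[str]]:
    """Habitats: lineage II supplies no amino acids (fully protected);
    I and III each supply one of the convergent pair plus an auxiliary;
    IV supplies every amino acid (deepest decay)."""
    aa = {p.name: universe.aa_nutrient(p.name) for p in universe.pathways}
    extra = [n for n in universe.pathway_names
             if n not in ("his_like", "trp_like")]
    env_i = {aa["trp_like"]} | {aa[extra[0]]} if extra else {aa["trp_like"]}
    env_iii = {aa["his_like"]} | ({aa[extra[1]]} if len(extra) > 1 else set())
    return {
        "lineage_I": frozenset(env_i),
        "lineage_II": frozenset(),
        "lineage_III": frozenset(env_iii),
        "lineage_IV": frozenset(aa.values()),
    }


def default_scenario(seed: int = 0, n_per_lineage: int = 5,
                     loss_rate: float = 2.0, n_discordant: int = 0
                     ) -> DecayScenario:
    """The package's standard 20-genome, 4-lineage decay scenario."""
    universe = generate_universe(seed=seed)
    newick, tree = default_tree(n_per_lineage)
    return simulate_decay(
        universe, tree, default_environments(universe),
        loss_rate=loss_rate, seed=seed, n_discordant=n_discordant,
        clade_omegas=dict(DEFAULT_CLADE_OMEGAS), newick=newick)


# ---------------------------------------------------------------------------
# codon evolution


@dataclass
class CodonSimulation:
    alignment: CodonAlignment
    root_sequence: str
    #: realized and proposed substitution counts per governing clade label
    counts: dict[str, dict[str, int]]
    clade_omegas: dict[str, float]
    seed: int


_SENSE_LIST = sorted(SENSE_CODONS)


def simulate_codon_evolution(
    phylogeny: Phylogeny,
    root_length: int = 300,
    clade_omegas: dict[str, float] | None = None,
    mutation_rate: float = 1.0,
    seed: int = 0,
    default_omega: float = 1.0,
) -> CodonSimulation:
    """Evolve a codon sequence along the tree.

    ``mutation_rate`` is the expected number of proposed point mutations
    per nucleotide site per unit branch length.  Proposals creating stop
    codons are rejected outright; synonymous changes fix with probability
    1, nonsynonymous ones with the omega of the clade containing the
    branch (``default_omega`` outside labeled clades).  Substitution
    bookkeeping per clade label supports closed-form rate checks.
    """
    clade_omegas = dict(clade_omegas or {})
    for label, omega in clade_omegas.items():
        if omega <= 0:
            raise ValueError(f"clade {label!r}: omega must be > 0")
        phylogeny.clade_leaves(label)
    rng = np.random.default_rng(seed)
    root = [_SENSE_LIST[i] for i in
            rng.integers(0, len(_SENSE_LIST), size=root_length)]

    def governing(node) -> str:
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        for label in sorted(clade_omegas):
            if leaves <= phylogeny.clades[label]:
                return label
        return "__default__"

    counts: dict[str, dict[str, int]] = {}

    def bucket(label):
        return counts.setdefault(label, {
            "syn_fixed": 0, "nonsyn_fixed": 0,
            "syn_proposed": 0, "nonsyn_proposed": 0, "stop_rejected": 0})

    seqs_at = {id(phylogeny.tree.seed_node): root}
    leaf_seqs: dict[str, str] = {}
    for node in phylogeny.tree.preorder_node_iter():
        if node is phylogeny.tree.seed_node:
            continue
        seq = list(seqs_at[id(node.parent_node)])
        bl = node.edge.length or 0.0
        label = governing(node)
        omega = clade_omegas.get(label, default_omega)
        b = bucket(label)
        n_events = rng.poisson(mutation_rate * 3 * root_length * bl)
        for _ in range(n_events):
            site = int(rng.integers(0, 3 * root_length))
            ci, pos = divmod(site, 3)
            codon = seq[ci]
            alternatives = [n for n in "ACGT" if n != codon[pos]]
            nt = alternatives[int(rng.integers(0, 3))]
            new = codon[:pos] + nt + codon[pos + 1:]
            if new in STOP_CODONS:
                b["stop_rejected"] += 1
                continue
            if CODON_TO_AA[new] == CODON_TO_AA[codon]:
                b["syn_proposed"] += 1
                b["syn_fixed"] += 1
                seq[ci] = new
            else:
                b["nonsyn_proposed"] += 1
                if rng.random() < omega:
                    b["nonsyn_fixed"] += 1
                    seq[ci] = new
        seqs_at[id(node)] = seq
        if node.is_leaf():
            leaf_seqs[node.taxon.label] = "".join(seq)

    return CodonSimulation(
        alignment=CodonAlignment(sequences=leaf_seqs),
        root_sequence="".join(root),
        counts=counts,
        clade_omegas=clade_omegas,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# homology-hit emulation and fixture emission


def hit_table(scenario: DecayScenario) -> pd.DataFrame:
    """Synthetic all-vs-all homology hits: genes hit genes of the same
    functional role in every other genome (strong score), emulating a
    BLAST tabular output for the ortholog-calling stage."""
    rows = []
    genomes = sorted(scenario.genomes)
    for qg in genomes:
        q_by_role = {role: gene for gene, role in scenario.genomes[qg].genes}
        for sg in genomes:
            if qg == sg:
                continue
            for gene, role in scenario.genomes[sg].genes:
                if role in q_by_role:
                    rows.append((q_by_role[role], gene, qg, sg, 200.0, 1e-50))
    return pd.DataFrame(rows, columns=[
        "query_gene", "subject_gene", "query_genome", "subject_genome",
        "bitscore", "evalue"])


def emit_fixtures(scenario: DecayScenario, out_dir,
                  codon_sim: CodonSimulation | None = None) -> list[str]:
    """Write every artifact the pipeline consumes; byte-deterministic.

    Returns the manifest (relative file names, sorted).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_database(scenario.universe.db, out / "universe.json")
    write_annotations(
        [scenario.genomes[g] for g in sorted(scenario.genomes)],
        out / "annotations.tsv")
    (out / "tree.nwk").write_text(scenario.newick + "\n")
    (out / "pathways.json").write_text(json.dumps({
        "pathways": [
            {"name": p.name,
             "expected_roles": sorted(p.expected_roles),
             "completeness_threshold": str(p.completeness_threshold),
             "shared_roles": sorted(p.shared_roles)}
            for p in scenario.universe.pathways],
        "focal_role": scenario.universe.focal_role,
        "nutrient_pathway_map": dict(sorted(
            scenario.universe.nutrient_pathway_map.items())),
    }, indent=1, sort_keys=True) + "\n")
    (out / "environments.json").write_text(json.dumps(
        {l: sorted(v) for l, v in sorted(scenario.environments.items())},
        indent=1, sort_keys=True) + "\n")
    (out / "truth.json").write_text(json.dumps({
        "seed": scenario.seed,
        "loss_rate": scenario.loss_rate,
        "n_discordant": scenario.n_discordant,
        "clade_omegas": scenario.clade_omegas,
        "genomes": scenario.truth,
    }, indent=1, sort_keys=True) + "\n")
    hit_table(scenario).to_csv(out / "hits.tsv", sep="\t", index=False)
    manifest = ["annotations.tsv", "environments.json", "hits.tsv",
                "pathways.json", "tree.nwk", "truth.json", "universe.json"]
    if codon_sim is not None:
        write_fasta(dict(sorted(codon_sim.alignment.sequences.items())),
                    out / "focal_cds.fasta")
        manifest.append("focal_cds.fasta")
    return sorted(manifest)


# ---------------------------------------------------------------------------
# small random networks for the oracle battery


def random_toy_network(seed: int) -> StoichiometricModel:
    """A random viable flux network with at most 8 reactions.

    Draws one of four motifs — linear chain, two substitutable nutrient
    routes, two jointly required nutrients, or a chain with a futile
    loop — optionally with a duplicated chain step and 2:1 stoichiometry,
    always growing on its complete medium.  Sized for exhaustive
    vertex-enumeration cross-checks.
    """
    rng = np.random.default_rng(seed)
    mets: dict[str, Metabolite] = {}
    reactions: dict[str, Reaction] = {}

    def met(mid, comp=CYTOSOL):
        mets[mid] = Metabolite(id=mid, name=mid, compartment=comp)

    def rxn(rid, stoich, gene=True, lb=0.0, ub=FLUX_MAX, exchange=False):
        reactions[rid] = Reaction(
            id=rid, stoichiometry={m: Fraction(c) for m, c in stoich.items()},
            lower_bound=lb, upper_bound=ub,
            gene_association=((f"g_{rid}",),) if gene else (),
            is_exchange=exchange)

    def nutrient(label):
        met(f"{label}_e", EXTRACELLULAR)
        met(f"{label}_c")
        rxn(f"EX_{label}_e", {f"{label}_e": -1}, gene=False,
            lb=-10.0, exchange=True)
        rxn(f"T_{label}", {f"{label}_e": -1, f"{label}_c": 1})

    met("P_c")
    motif = int(rng.integers(0, 4))
    coef = 2 if rng.random() < 0.3 else 1
    if motif == 0:  # linear chain, possibly duplicated step
        nutrient("A")
        rxn("R1", {"A_c": -coef, "P_c": 1})
        if rng.random() < 0.5:
            rxn("R1b", {"A_c": -coef, "P_c": 1})
        if rng.random() < 0.5:
            met("X_c")
            rxn("R2", {"P_c": -1, "X_c": 1})
            rxn("BIO", {"X_c": -1}, gene=False)
        else:
            rxn("BIO", {"P_c": -1}, gene=False)
    elif motif == 1:  # substitutable routes from two nutrients
        nutrient("A")
        nutrient("B")
        rxn("R1a", {"A_c": -coef, "P_c": 1})
        rxn("R1b", {"B_c": -1, "P_c": 1})
        rxn("BIO", {"P_c": -1}, gene=False)
    elif motif == 2:  # two jointly required precursors
        nutrient("A")
        nutrient("B")
        met("Q_c")
        rxn("R1", {"A_c": -coef, "P_c": 1})
        rxn("R2", {"B_c": -1, "Q_c": 1})
        rxn("BIO", {"P_c": -1, "Q_c": -1}, gene=False)
    else:  # chain with a futile loop off the growth path
        nutrient("A")
        met("X_c")
        rxn("R1", {"A_c": -coef, "P_c": 1})
        rxn("L1", {"P_c": -1, "X_c": 1})
        rxn("L2", {"X_c": -1, "P_c": 1})
        rxn("BIO", {"P_c": -1}, gene=False)

    model = StoichiometricModel(
        genome_id=f"toy{seed}", metabolites=mets, reactions=reactions,
        biomass_reaction_id="BIO")
    assert len(reactions) <= 8
    return model


def random_gapfill_case(seed: int
                        ) -> tuple[StoichiometricModel, UniversalDatabase]:
    """A draft model with 1-2 internal reactions knocked out plus a
    universal database holding the full network and dead-end decoys."""
    rng = np.random.default_rng(seed + 10_000)
    base = random_toy_network(seed)

    db_mets = dict(base.metabolites)
    db_rxns = {}
    for rid, r in base.reactions.items():
        if not r.is_exchange:
            db_rxns[rid] = Reaction(
                id=rid, stoichiometry=r.stoichiometry,
                lower_bound=r.lower_bound, upper_bound=r.upper_bound)
    for d in ("dead1_c", "dead2_c"):
        db_mets[d] = Metabolite(id=d, name=d, compartment=CYTOSOL)
    db_rxns["D1"] = Reaction(id="D1", stoichiometry={"P_c": Fraction(-1),
                                                     "dead1_c": Fraction(1)},
                             lower_bound=0.0, upper_bound=FLUX_MAX)
    db_rxns["D2"] = Reaction(id="D2", stoichiometry={"dead1_c": Fraction(-1),
                                                     "dead2_c": Fraction(1)},
                             lower_bound=0.0, upper_bound=FLUX_MAX)
    db = UniversalDatabase(
        metabolites=db_mets, reactions=db_rxns, role_map={},
        transportable=frozenset(base.exchangeable_metabolites),
        biomass_reaction_id="BIO")

    removable = sorted(
        rid for rid, r in base.reactions.items()
        if not r.is_exchange and rid != "BIO")
    n_remove = int(rng.integers(1, min(2, len(removable)) + 1))
    removed = sorted(rng.choice(removable, size=n_remove, replace=False))
    draft = base.copy()
    draft.genome_id = f"draft{seed}"
    for rid in removed:
        del draft.reactions[rid]
    return draft, db


def load_pathways(path) -> tuple[list[PathwayDefinition], dict[str, str], str]:
    """Read back the pathway definitions emitted by :func:`emit_fixtures`."""
    doc = json.loads(Path(path).read_text())
    pathways = [
        PathwayDefinition(
            name=p["name"],
            expected_roles=frozenset(p["expected_roles"]),
            completeness_threshold=Fraction(p["completeness_threshold"]),
            shared_roles=frozenset(p["shared_roles"]))
        for p in doc["pathways"]
    ]
    return pathways, doc["nutrient_pathway_map"], doc["focal_role"]
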