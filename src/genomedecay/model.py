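"""Domain types for metabolic models and draft-model construction.

A :class:`StoichiometricModel` is the object every flux-balance step acts
on: a set of metabolites split over two compartments (cytosol,
extracellular), a set of reactions with rational stoichiometries, flux
bounds and gene associations, and one designated biomass reaction.  A
:class:`UniversalDatabase` is the template biochemistry from which draft
models are built by role lookup and from which gapfilling may borrow
reactions.

Sign conventions
----------------
Exchange reactions have stoichiometry ``{met_e: -1}``; negative flux is
uptake (the metabolite enters the system), positive flux is secretion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

CYTOSOL = "cytosol"
EXTRACELLULAR = "extracellular"
COMPARTMENTS = (CYTOSOL, EXTRACELLULAR)

#: Disjunction of conjunctions of gene ids, e.g. ``[["g1"], ["g2", "g3"]]``
#: means g1 OR (g2 AND g3).  Nesting deeper than conjunctive pairs is
#: rejected at parse time.
GeneAssociation = tuple[tuple[str, ...], ...]


class ModelValidationError(ValueError):
    """A model violates a structural invariant."""


class ModelParseError(ValueError):
    """A model file does not parse under the documented dialect."""


@dataclass(frozen=True, order=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = CYTOSOL

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ModelValidationError(
                f"metabolite {self.id!r}: compartment {self.compartment!r} "
                f"not in {COMPARTMENTS}"
            )


def normalize_gpr(gpr: Iterable[Iterable[str]] | None) -> GeneAssociation:
    """Canonicalize a gene association: sorted conjunctions, sorted terms.

    Conjunctions are limited to pairs (single genes or two-gene AND terms).
    """
    if not gpr:
        return ()
    terms = []
    for conj in gpr:
        genes = tuple(sorted(set(conj)))
        if not genes:
            continue
        if len(genes) > 2:
            raise ModelValidationError(
                f"gene association conjunction {genes} has more than two "
                "genes; only single genes or conjunctive pairs are supported"
            )
        terms.append(genes)
    return tuple(sorted(set(terms)))


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction with bounds and a gene association.

    ``stoichiometry`` maps metabolite id to a signed rational coefficient
    (negative = consumed, positive = produced).
    """

    id: str
    stoichiometry: Mapping[str, Fraction]
    lower_bound: float
    upper_bound: float
    gene_association: GeneAssociation = ()
    gapfilled: bool = False
    is_exchange: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "stoichiometry",
            {m: Fraction(c) for m, c in dict(self.stoichiometry).items()},
        )
        object.__setattr__(
            self, "gene_association", normalize_gpr(self.gene_association)
        )

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for conj in self.gene_association for g in conj)

    @property
    def is_gene_associated(self) -> bool:
        return bool(self.gene_association)

    def with_genes(self, gpr: Iterable[Iterable[str]]) -> "Reaction":
        return replace(self, gene_association=normalize_gpr(gpr))

    def violations(self, metabolites: Mapping[str, Metabolite] | None = None
                   ) -> list[str]:
        out = []
        if self.lower_bound > self.upper_bound:
            out.append(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            out.append(f"reaction {self.id!r}: empty stoichiometry")
        if self.gapfilled and self.gene_association:
            out.append(
                f"reaction {self.id!r}: gapfilled but has a gene association"
            )
        if metabolites is not None:
            missing = sorted(set(self.stoichiometry) - set(metabolites))
            for m in missing:
                out.append(
                    f"reaction {self.id!r}: references unknown metabolite {m!r}"
                )
            if self.is_exchange and not missing:
                ext = [
                    m for m in self.stoichiometry
                    if metabolites[m].compartment == EXTRACELLULAR
                ]
                if len(self.stoichiometry) != 1 or len(ext) != 1:
                    out.append(
                        f"reaction {self.id!r}: exchange reactions must touch "
                        "exactly one extracellular metabolite"
                    )
        return out

    @property
    def exchanged_metabolite(self) -> str:
        if not self.is_exchange or len(self.stoichiometry) != 1:
            raise ValueError(f"reaction {self.id!r} is not a simple exchange")
        return next(iter(self.stoichiometry))


@dataclass(frozen=True)
class Medium:
    """A set of extracellular nutrient ids with a shared uptake limit."""

    nutrients: frozenset[str]
    uptake_limit: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "nutrients", frozenset(self.nutrients))
        if self.uptake_limit <= 0:
            raise ModelValidationError("uptake_limit must be > 0")


@dataclass
class StoichiometricModel:
    genome_id: str
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    biomass_reaction_id: str

    @classmethod
    def from_components(
        cls,
        genome_id: str,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        biomass_reaction_id: str,
    ) -> "StoichiometricModel":
        return cls(
            genome_id=genome_id,
            metabolites={m.id: m for m in metabolites},
            reactions={r.id: r for r in reactions},
            biomass_reaction_id=biomass_reaction_id,
        )

    # -- canonical orderings -------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return sorted(self.reactions)

    @property
    def metabolite_ids(self) -> list[str]:
        return sorted(self.metabolites)

    @property
    def exchange_reactions(self) -> list[Reaction]:
        return [self.reactions[r] for r in self.reaction_ids
                if self.reactions[r].is_exchange]

    @property
    def exchangeable_metabolites(self) -> frozenset[str]:
        return frozenset(r.exchanged_metabolite for r in self.exchange_reactions)

    def gene_associated_reaction_ids(self) -> frozenset[str]:
        return frozenset(
            r for r in self.reactions if self.reactions[r].is_gene_associated
        )

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S (metabolites x reactions) plus canonical row/column ids."""
        mets, rxns = self.metabolite_ids, self.reaction_ids
        mi = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(rxns)))
        for j, rid in enumerate(rxns):
            for m, c in self.reactions[rid].stoichiometry.items():
                S[mi[m], j] = float(c)
        return S, mets, rxns

    def copy(self) -> "StoichiometricModel":
        return StoichiometricModel(
            genome_id=self.genome_id,
            metabolites=dict(self.metabolites),
            reactions=dict(self.reactions),
            biomass_reaction_id=self.biomass_reaction_id,
        )


def validate_model(model: StoichiometricModel) -> list[str]:
    """Return human-readable invariant violations; empty iff the model is valid."""
    out: list[str] = []
    if not model.reactions:
        out.append(f"model {model.genome_id!r}: no reactions")
    if model.biomass_reaction_id not in model.reactions:
        out.append(
            f"model {model.genome_id!r}: biomass reaction "
            f"{model.biomass_reaction_id!r} not present"
        )
    for mid, met in model.metabolites.items():
        if mid != met.id:
            out.append(f"metabolite key {mid!r} != id {met.id!r}")
    for rid, rxn in model.reactions.items():
        if rid != rxn.id:
            out.append(f"reaction key {rid!r} != id {rxn.id!r}")
        out.extend(rxn.violations(model.metabolites))
    return out


def require_valid(model: StoichiometricModel) -> None:
    problems = validate_model(model)
    if problems:
        raise ModelValidationError("; ".join(problems))


@dataclass
class UniversalDatabase:
    """Template biochemistry: reactions, role->reaction map, transportables.

    ``transportable`` lists the extracellular metabolites for which every
    draft model receives an exchange reaction; a medium "containing every
    transportable metabolite" is the complete medium.
    """

    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    role_map: dict[str, frozenset[str]]
    transportable: frozenset[str]
    biomass_reaction_id: str

    def __post_init__(self) -> None:
        self.role_map = {r: frozenset(v) for r, v in self.role_map.items()}
        self.transportable = frozenset(self.transportable)

    def validate(self) -> list[str]:
        out = []
        for role, rids in sorted(self.role_map.items()):
            for rid in sorted(rids):
                if rid not in self.reactions:
                    out.append(
                        f"role {role!r} maps to unknown reaction {rid!r}")
        for m in sorted(self.transportable):
            met = self.metabolites.get(m)
            if met is None or met.compartment != EXTRACELLULAR:
                out.append(
                    f"transportable {m!r} is not an extracellular metabolite "
                    "of the database"
                )
        if self.biomass_reaction_id not in self.reactions:
            out.append(
                f"biomass template {self.biomass_reaction_id!r} missing")
        for rxn in self.reactions.values():
            out.extend(rxn.violations(self.metabolites))
        return out

    def complete_medium(self, uptake_limit: float = 10.0) -> Medium:
        return Medium(nutrients=self.transportable, uptake_limit=uptake_limit)


@dataclass(frozen=True)
class GenomeAnnotation:
    """Functional annotation: ordered (gene_id, functional_role) pairs."""

    genome_id: str
    genes: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(tuple(g) for g in self.genes))
        ids = [g for g, _ in self.genes]
        if len(ids) != len(set(ids)):
            dup = sorted({g for g in ids if ids.count(g) > 1})
            raise ModelValidationError(
                f"annotation {self.genome_id!r}: duplicate gene ids {dup}")

    @property
    def roles(self) -> frozenset[str]:
        return frozenset(role for _, role in self.genes)

    def genes_for_role(self, role: str) -> list[str]:
        return sorted(g for g, r in self.genes if r == role)


def exchange_reaction(met_id: str, uptake_limit: float = 10.0,
                      secretion_limit: float = 1000.0) -> Reaction:
    """Build the canonical exchange reaction ``EX_<met>`` for a metabolite."""
    return Reaction(
        id=f"EX_{met_id}",
        stoichiometry={met_id: Fraction(-1)},
        lower_bound=-uptake_limit,
        upper_bound=secretion_limit,
        is_exchange=True,
    )


def build_model_from_annotation(
    annotation: GenomeAnnotation,
    db: UniversalDatabase,
    uptake_limit: float = 10.0,
) -> StoichiometricModel:
    """Construct a draft model: db reactions whose roles appear in the
    annotation, plus exchanges for every transportable metabolite and the
    database biomass template.

    Gene associations are filled as a disjunction over the annotated genes
    carrying any role that maps to the reaction.  Annotation roles absent
    from the role map are ignored with a warning — they are simply functions
    the template biochemistry does not cover.
    """
    problems = db.validate()
    if problems:
        raise ModelValidationError("invalid database: " + "; ".join(problems))

    rxn_genes: dict[str, set[str]] = {}
    for role in sorted(annotation.roles):
        rids = db.role_map.get(role)
        if rids is None:
            logger.warning(
                "annotation %s: role %r not in database role map; ignored",
                annotation.genome_id, role)
            continue
        for rid in rids:
            rxn_genes.setdefault(rid, set()).update(
                annotation.genes_for_role(role))

    reactions: dict[str, Reaction] = {}
    for rid in sorted(rxn_genes):
        template = db.reactions[rid]
        reactions[rid] = template.with_genes([[g] for g in sorted(rxn_genes[rid])])
    for met in sorted(db.transportable):
        ex = exchange_reaction(met, uptake_limit=uptake_limit)
        reactions[ex.id] = ex
    biomass = db.reactions[db.biomass_reaction_id]
    reactions[biomass.id] = biomass

    used = {m for r in reactions.values() for m in r.stoichiometry}
    metabolites = {m: db.metabolites[m] for m in used}
    model = StoichiometricModel(
        genome_id=annotation.genome_id,
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id=db.biomass_reaction_id,
    )
    require_valid(model)
    return model
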