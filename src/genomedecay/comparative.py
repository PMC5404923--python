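"""Cross-model comparison: reaction prevalence, lineage core models,
overlap partitions and conserved-core containment.

A lineage core model keeps the reactions that are gene-associated in at
least 75% of the lineage's models (inclusive, compared with exact
rationals so that 3 of 4 qualifies), is gapfilled on the complete medium,
and can then be run through the six-step flux-balance analysis like any
genome model.  The cross-lineage conserved core is the intersection of
gene-associated reaction sets over all models.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .gapfilling import GapfillSolution, apply_gapfill, gapfill
from .model import StoichiometricModel, UniversalDatabase


@dataclass
class PresenceMatrix:
    """Binary genomes-by-features matrix backed by a pandas DataFrame."""

    values: pd.DataFrame  # rows = genomes/models, columns = features, 0/1
    feature_kind: str  # "reaction" | "pathway" | "gene"

    def __post_init__(self) -> None:
        if self.feature_kind not in ("reaction", "pathway", "gene"):
            raise ValueError(f"bad feature_kind {self.feature_kind!r}")
        v = self.values.astype(int)
        if not v.isin((0, 1)).all().all():
            raise ValueError("presence matrix must be binary")
        self.values = v

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def column_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self) -> str:
        return self.values.to_csv(sep="\t")


def reaction_prevalence(
    models: Sequence[StoichiometricModel],
    gene_associated_only: bool = True,
) -> tuple[PresenceMatrix, dict[str, Fraction]]:
    """Presence matrix over reactions plus per-reaction prevalence fraction.

    With ``gene_associated_only`` (the default, matching how gapfilled
    reactions are excluded from comparative analyses) a reaction counts as
    present only where it carries a gene association.
    """
    if not models:
        raise ValueError("need at least one model")
    sets = {}
    for m in models:
        if gene_associated_only:
            sets[m.genome_id] = m.gene_associated_reaction_ids()
        else:
            sets[m.genome_id] = frozenset(m.reactions)
    features = sorted(set().union(*sets.values()))
    df = pd.DataFrame(
        [[int(f in sets[g]) for f in features] for g in sets],
        index=list(sets), columns=features, dtype=int)
    n = len(models)
    prevalence = {f: Fraction(int(df[f].sum()), n) for f in features}
    return PresenceMatrix(values=df, feature_kind="reaction"), prevalence


def core_reaction_set(
    models: Sequence[StoichiometricModel],
    threshold: Fraction | float = Fraction(3, 4),
) -> frozenset[str]:
    """Reactions gene-associated in at least ``threshold`` of the models."""
    thr = Fraction(threshold)
    _, prevalence = reaction_prevalence(models, gene_associated_only=True)
    return frozenset(r for r, p in prevalence.items() if p >= thr)


def lineage_core_model(
    models: Sequence[StoichiometricModel],
    db: UniversalDatabase,
    threshold: Fraction | float = Fraction(3, 4),
    lineage_id: str = "lineage_core",
    uptake_limit: float = 10.0,
) -> tuple[StoichiometricModel, GapfillSolution]:
    """Build, gapfill and return the core model of a lineage.

    Core reactions keep a merged gene association (union of the member
    models' disjunction terms); gapfilled additions are flagged as such.
    """
    if len(models) < 2:
        raise ValueError("a lineage core needs at least two models")
    core = core_reaction_set(models, threshold)

    merged_gpr: dict[str, set] = {r: set() for r in core}
    for m in models:
        for rid in core:
            rxn = m.reactions.get(rid)
            if rxn is not None and rxn.is_gene_associated:
                merged_gpr[rid].update(rxn.gene_association)

    reactions = {}
    metabolites = {}
    for rid in sorted(core):
        template = db.reactions[rid]
        reactions[rid] = template.with_genes(sorted(merged_gpr[rid]))
        for met in template.stoichiometry:
            metabolites[met] = db.metabolites[met]
    biomass = db.reactions[db.biomass_reaction_id]
    reactions[biomass.id] = biomass
    for met in biomass.stoichiometry:
        metabolites[met] = db.metabolites[met]

    draft = StoichiometricModel(
        genome_id=lineage_id, metabolites=metabolites, reactions=reactions,
        biomass_reaction_id=db.biomass_reaction_id)
    solution = gapfill(draft, db, uptake_limit=uptake_limit)
    model = apply_gapfill(draft, db, solution.added_reaction_ids,
                          uptake_limit=uptake_limit)
    return model, solution


def global_conserved_core(models: Sequence[StoichiometricModel]
                          ) -> frozenset[str]:
    """Reactions gene-associated in every model (cross-lineage core)."""
    sets = [m.gene_associated_reaction_ids() for m in models]
    return frozenset(frozenset.intersection(*sets)) if sets else frozenset()


def overlap_partition(sets: Mapping[str, Iterable[str]]
                      ) -> dict[str, int]:
    """Counts of every nonempty membership region over 2-4 sets.

    Region keys join member labels with ``&`` (e.g. ``"A&B"`` is the set of
    elements in A and B but no other set); counts sum to the union size.
    """
    labels = sorted(sets)
    if not 2 <= len(labels) <= 4:
        raise ValueError("overlap_partition supports 2 to 4 sets")
    as_sets = {l: frozenset(sets[l]) for l in labels}
    out: dict[str, int] = {}
    for k in range(1, len(labels) + 1):
        for inside in combinations(labels, k):
            region = frozenset.intersection(*(as_sets[l] for l in inside))
            for l in labels:
                if l not in inside:
                    region = region - as_sets[l]
            out["&".join(inside)] = len(region)
    return out


def core_containment(
    lineage_cores: Mapping[str, Iterable[str]],
    global_core: Iterable[str],
) -> dict[str, float]:
    """Per-lineage fraction of the lineage core contained in the global core."""
    g = frozenset(global_core)
    out = {}
    for lineage, core in sorted(lineage_cores.items()):
        c = frozenset(core)
        if not c:
            raise ValueError(f"lineage {lineage!r} has an empty core")
        out[lineage] = len(c & g) / len(c)
    return out


def core_containment_summary(
    lineage_cores: Mapping[str, Iterable[str]],
    global_core: Iterable[str],
) -> dict[str, float]:
    """Mean-over-lineages and pooled containment summaries."""
    per = core_containment(lineage_cores, global_core)
    g = frozenset(global_core)
    pooled_num = sum(len(frozenset(c) & g) for c in lineage_cores.values())
    pooled_den = sum(len(frozenset(c)) for c in lineage_cores.values())
    return {
        "mean": sum(per.values()) / len(per),
        "pooled": pooled_num / pooled_den,
    }
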