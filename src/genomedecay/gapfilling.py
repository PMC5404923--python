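"""Minimal-set gapfilling against a universal reaction database.

Finds the smallest set of database reactions whose addition lets a draft
model produce biomass on the complete medium (every transportable
metabolite supplied).  Among minimum-cardinality solutions the one
permitting the most gene-associated model reactions to carry flux is
preferred; remaining ties break to the lexicographically smallest id set.
Added reactions are flagged ``gapfilled`` and carry no gene association.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np

from . import _lp
from .fba import EPS_FLUX, _System, maximize_biomass
from .model import Medium, StoichiometricModel, UniversalDatabase, \
    exchange_reaction


class GapfillError(RuntimeError):
    pass


class UniverseInsufficientError(GapfillError):
    """Even the full database cannot make the model grow."""


@dataclass(frozen=True)
class GapfillSolution:
    added_reaction_ids: frozenset[str]
    objective_cost: float
    grows_after: bool
    #: gene-associated model reactions able to carry flux after the addition
    flux_enabled_count: int = 0


def ensure_exchanges(model: StoichiometricModel, db: UniversalDatabase,
                     uptake_limit: float = 10.0) -> StoichiometricModel:
    """Return a copy with exchange reactions for every db transportable."""
    out = model.copy()
    for met in sorted(db.transportable):
        ex = exchange_reaction(met, uptake_limit=uptake_limit)
        if ex.id not in out.reactions:
            out.reactions[ex.id] = ex
            out.metabolites.setdefault(met, db.metabolites[met])
    return out


def apply_gapfill(model: StoichiometricModel, db: UniversalDatabase,
                  added_ids, uptake_limit: float = 10.0
                  ) -> StoichiometricModel:
    """Augment a model with db reactions, flagged as gapfilled."""
    out = ensure_exchanges(model, db, uptake_limit)
    for rid in sorted(added_ids):
        template = db.reactions[rid]
        out.reactions[rid] = replace(template, gene_association=(),
                                     gapfilled=True)
        for met in template.stoichiometry:
            out.metabolites.setdefault(met, db.metabolites[met])
    return out


def _grows(model, db, added_ids, growth_floor, uptake_limit) -> bool:
    aug = apply_gapfill(model, db, added_ids, uptake_limit)
    fs = maximize_biomass(aug, db.complete_medium(uptake_limit))
    return fs.status == "optimal" and fs.objective_value >= growth_floor - 1e-9


def _flux_enabled_count(model, db, added_ids, growth_floor, uptake_limit,
                        epsilon) -> int:
    """Gene-associated model reactions that can carry flux while the
    augmented model grows at or above the floor on the complete medium."""
    aug = apply_gapfill(model, db, added_ids, uptake_limit)
    sys = _System(aug, db.complete_medium(uptake_limit))
    overrides = {aug.biomass_reaction_id: (growth_floor, np.inf)}
    count = 0
    for rid in sorted(model.gene_associated_reaction_ids()):
        st_hi, _, hi = sys.optimize({rid: 1.0}, "max", overrides)
        if st_hi == _lp.OPTIMAL and hi >= epsilon:
            count += 1
            continue
        st_lo, _, lo = sys.optimize({rid: 1.0}, "min", overrides)
        if st_lo == _lp.OPTIMAL and lo <= -epsilon:
            count += 1
    return count


def gapfill(
    model: StoichiometricModel,
    db: UniversalDatabase,
    growth_floor: float | None = None,
    uptake_limit: float = 10.0,
    epsilon: float = EPS_FLUX,
    max_enumerated: int = 200,
) -> GapfillSolution:
    """Two-stage minimal gapfilling on the complete medium.

    Stage 1 is an exact MILP for the minimum number of added reactions;
    stage 2 enumerates every cardinality-optimal set (no-good cuts) and
    keeps the one enabling the most gene-associated model reactions to
    carry flux, breaking ties lexicographically.

    ``growth_floor`` defaults to 10% of the fully-augmented model's maximum
    biomass on the complete medium.
    """
    candidates = sorted(
        rid for rid in db.reactions
        if rid not in model.reactions and rid != db.biomass_reaction_id
        and not db.reactions[rid].is_exchange
    )
    if growth_floor is None:
        full = apply_gapfill(model, db, candidates, uptake_limit)
        fs = maximize_biomass(full, db.complete_medium(uptake_limit))
        if fs.status != "optimal" or fs.objective_value <= epsilon:
            raise UniverseInsufficientError(
                f"model {model.genome_id!r}: universe insufficient for "
                "biomass production")
        growth_floor = 0.1 * fs.objective_value

    if _grows(model, db, (), growth_floor, uptake_limit):
        return GapfillSolution(
            added_reaction_ids=frozenset(), objective_cost=0.0,
            grows_after=True,
            flux_enabled_count=_flux_enabled_count(
                model, db, (), growth_floor, uptake_limit, epsilon))

    aug = apply_gapfill(model, db, candidates, uptake_limit)
    sys = _System(aug, db.complete_medium(uptake_limit))
    n, k = len(sys.rxn_ids), len(candidates)
    cand_j = [sys.index[r] for r in candidates]

    def stage1(cardinality: int | None, exclusions: list[frozenset[str]]):
        c = np.concatenate([np.zeros(n), np.ones(k)])
        A_eq = np.hstack([sys.S, np.zeros((sys.S.shape[0], k))])
        b_eq = np.zeros(sys.S.shape[0])
        rows, rhs = [], []
        for i, rid in enumerate(candidates):
            j = cand_j[i]
            ub = aug.reactions[rid].upper_bound
            lb = aug.reactions[rid].lower_bound
            if ub > 0:  # v_j - ub*z <= 0
                row = np.zeros(n + k); row[j] = 1.0; row[n + i] = -ub
                rows.append(row); rhs.append(0.0)
            if lb < 0:  # -v_j + lb*z <= 0
                row = np.zeros(n + k); row[j] = -1.0; row[n + i] = lb
                rows.append(row); rhs.append(0.0)
        for excl in exclusions:
            row = np.zeros(n + k)
            for i, rid in enumerate(candidates):
                if rid in excl:
                    row[n + i] = 1.0
            rows.append(row); rhs.append(len(excl) - 1.0)
        lo, hi = sys.bounds({aug.biomass_reaction_id: (growth_floor, np.inf)})
        # a candidate reaction may only carry flux when selected
        bounds = list(zip(lo, hi)) + [(0.0, 1.0)] * k
        for i, j in enumerate(cand_j):
            bounds[j] = (min(bounds[j][0], 0.0), max(bounds[j][1], 0.0))
        if cardinality is not None:
            row = np.concatenate([np.zeros(n), np.ones(k)])
            A_eq = np.vstack([A_eq, row])
            b_eq = np.append(b_eq, float(cardinality))
        integrality = np.concatenate([np.zeros(n), np.ones(k)])
        return _lp.solve_milp(c, integrality, A_eq, b_eq,
                              np.array(rows), np.array(rhs), bounds)

    status, x, fun = stage1(None, [])
    if status != _lp.OPTIMAL:
        raise UniverseInsufficientError(
            f"model {model.genome_id!r}: universe insufficient for "
            "biomass production")
    k_opt = int(round(fun))

    # enumerate all minimum-cardinality solutions via no-good cuts
    solutions: list[frozenset[str]] = []
    exclusions: list[frozenset[str]] = []
    while len(solutions) < max_enumerated:
        status, x, _ = stage1(k_opt, exclusions)
        if status != _lp.OPTIMAL:
            break
        chosen = frozenset(
            candidates[i] for i in range(k) if x[n + i] > 0.5)
        # solver-level roundoff guard: re-verify growth by plain LP
        if len(chosen) == k_opt and _grows(model, db, chosen, growth_floor,
                                           uptake_limit):
            solutions.append(chosen)
        exclusions.append(chosen)
    if not solutions:
        raise GapfillError("no verifiable minimum-cardinality solution")

    scored = sorted(
        (( -_flux_enabled_count(model, db, s, growth_floor, uptake_limit,
                                epsilon), tuple(sorted(s))), s)
        for s in solutions
    )
    best_key, best = scored[0]
    return GapfillSolution(
        added_reaction_ids=best,
        objective_cost=float(k_opt),
        grows_after=True,
        flux_enabled_count=-best_key[0],
    )


def verify_minimality(
    model: StoichiometricModel,
    db: UniversalDatabase,
    solution: GapfillSolution,
    growth_floor: float,
    uptake_limit: float = 10.0,
) -> bool:
    """Exhaustively confirm no strict subset of the solution (and, for
    solutions of size <= 3, no smaller db subset at all) restores growth."""
    sol = sorted(solution.added_reaction_ids)
    if len(sol) > 6:
        raise GapfillError(
            f"verify_minimality refuses |solution| = {len(sol)} > 6")
    if not _grows(model, db, sol, growth_floor, uptake_limit):
        return False
    for size in range(len(sol)):
        for sub in combinations(sol, size):
            if _grows(model, db, sub, growth_floor, uptake_limit):
                return False
    if len(sol) <= 3:
        candidates = sorted(
            rid for rid in db.reactions
            if rid not in model.reactions and rid != db.biomass_reaction_id
            and not db.reactions[rid].is_exchange)
        for size in range(len(sol)):
            for sub in combinations(candidates, size):
                if _grows(model, db, sub, growth_floor, uptake_limit):
                    return False
    return True
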