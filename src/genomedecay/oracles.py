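"""Exhaustive reference implementations for small problems.

These deliberately avoid the LP/MILP solver paths of the main engine:
flux optima come from enumerating the basic feasible solutions (vertices)
of the flux polytope, media and gapfill sets from exhaustive subset
search, and codon distances from naive mutational-pathway enumeration
with per-step translation.  They are exponential-time and only intended
for networks of at most ~10 reactions and short alignments, where they
serve as ground truth for the polished implementations.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations, permutations, product

import numpy as np
from Bio.Seq import Seq

from .gapfilling import apply_gapfill
from .model import Medium, StoichiometricModel, UniversalDatabase

_TOL = 1e-7


def _arrays(model: StoichiometricModel, medium: Medium,
            overrides: dict[str, tuple[float, float]] | None = None):
    """S, bounds and id maps under the documented medium convention
    (exchange lower bound = -uptake for medium nutrients, else 0)."""
    rxns = sorted(model.reactions)
    mets = sorted(model.metabolites)
    mi = {m: i for i, m in enumerate(mets)}
    S = np.zeros((len(mets), len(rxns)))
    lo = np.zeros(len(rxns))
    hi = np.zeros(len(rxns))
    for j, rid in enumerate(rxns):
        r = model.reactions[rid]
        for m, c in r.stoichiometry.items():
            S[mi[m], j] = float(c)
        if r.is_exchange:
            met = r.exchanged_metabolite
            lo[j] = -medium.uptake_limit if met in medium.nutrients else 0.0
            hi[j] = r.upper_bound
        else:
            lo[j], hi[j] = r.lower_bound, r.upper_bound
    for rid, (a, b) in (overrides or {}).items():
        j = rxns.index(rid)
        lo[j] = max(lo[j], a)
        hi[j] = min(hi[j], b)
    return S, lo, hi, rxns


def enumerate_vertices(S: np.ndarray, lo: np.ndarray, hi: np.ndarray
                       ) -> list[np.ndarray]:
    """All vertices of {v : S v = 0, lo <= v <= hi} (finite bounds)."""
    m, n = S.shape
    r = np.linalg.matrix_rank(S, tol=1e-10) if m else 0
    nfix = n - r
    vertices: list[np.ndarray] = []
    for fixed in combinations(range(n), nfix):
        free = [j for j in range(n) if j not in fixed]
        A = S[:, free]
        if free and np.linalg.matrix_rank(A, tol=1e-10) < len(free):
            continue
        side_choices = []
        for j in fixed:
            side_choices.append((lo[j],) if lo[j] == hi[j]
                                else (lo[j], hi[j]))
        for sides in product(*side_choices):
            v = np.empty(n)
            v[list(fixed)] = sides
            if free:
                b = -S[:, list(fixed)] @ np.array(sides) if fixed \
                    else np.zeros(m)
                sol, *_ = np.linalg.lstsq(A, b, rcond=None)
                v[free] = sol
            if np.max(np.abs(S @ v), initial=0.0) > _TOL:
                continue
            if np.all(v >= lo - _TOL) and np.all(v <= hi + _TOL):
                vertices.append(np.clip(v, lo, hi))
    return vertices


def max_biomass_vertices(model, medium, overrides=None) -> float | None:
    """Maximum biomass flux over enumerated vertices; None if infeasible."""
    S, lo, hi, rxns = _arrays(model, medium, overrides)
    verts = enumerate_vertices(S, lo, hi)
    if not verts:
        return None
    j = rxns.index(model.biomass_reaction_id)
    return max(float(v[j]) for v in verts)


def fva_vertices(model, medium, overrides=None
                 ) -> dict[str, tuple[float, float]]:
    """Per-reaction flux ranges over enumerated vertices."""
    S, lo, hi, rxns = _arrays(model, medium, overrides)
    verts = enumerate_vertices(S, lo, hi)
    if not verts:
        raise ValueError("infeasible polytope")
    V = np.array(verts)
    return {rid: (float(V[:, j].min()), float(V[:, j].max()))
            for j, rid in enumerate(rxns)}


def minimal_media_bruteforce(model, growth_floor: float,
                             uptake_limit: float = 10.0) -> frozenset[str]:
    """First growing nutrient subset in (cardinality, lexicographic) order."""
    nutrients = sorted(
        model.reactions[r].exchanged_metabolite
        for r in model.reactions if model.reactions[r].is_exchange)
    for size in range(len(nutrients) + 1):
        for subset in combinations(nutrients, size):
            medium = Medium(nutrients=frozenset(subset),
                            uptake_limit=uptake_limit)
            vmax = max_biomass_vertices(model, medium)
            if vmax is not None and vmax >= growth_floor - _TOL:
                return frozenset(subset)
    raise ValueError("no nutrient subset supports growth")


def _flux_enabled_vertices(model, db, added, growth_floor, uptake_limit,
                           epsilon) -> int:
    aug = apply_gapfill(model, db, added, uptake_limit)
    medium = db.complete_medium(uptake_limit)
    overrides = {aug.biomass_reaction_id: (growth_floor, np.inf)}
    ranges = fva_vertices(aug, medium, overrides)
    count = 0
    for rid in sorted(model.gene_associated_reaction_ids()):
        lo, hi = ranges[rid]
        if hi >= epsilon or lo <= -epsilon:
            count += 1
    return count


def gapfill_bruteforce(
    model: StoichiometricModel,
    db: UniversalDatabase,
    growth_floor: float,
    uptake_limit: float = 10.0,
    epsilon: float = 1e-6,
    max_size: int = 3,
) -> frozenset[str]:
    """Exhaustive subset search mirroring the gapfill objective: smallest
    added set, then most gene-associated model reactions able to carry
    flux, then lexicographic."""
    medium = db.complete_medium(uptake_limit)
    candidates = sorted(
        rid for rid in db.reactions
        if rid not in model.reactions and rid != db.biomass_reaction_id
        and not db.reactions[rid].is_exchange)

    def grows(subset) -> bool:
        aug = apply_gapfill(model, db, subset, uptake_limit)
        vmax = max_biomass_vertices(aug, medium)
        return vmax is not None and vmax >= growth_floor - _TOL

    for size in range(max_size + 1):
        hits = [frozenset(s) for s in combinations(candidates, size)
                if grows(s)]
        if not hits:
            continue
        scored = sorted(
            ((-_flux_enabled_vertices(model, db, s, growth_floor,
                                      uptake_limit, epsilon),
              tuple(sorted(s))), s)
            for s in hits)
        return scored[0][1]
    raise ValueError(f"no subset of size <= {max_size} restores growth")


def pfba_bruteforce(model, medium, biomass_value: float) -> float:
    """Minimum total absolute flux at fixed biomass, by enumerating sign
    orthants of reversible reactions and vertices within each."""
    S, lo, hi, rxns = _arrays(
        model, medium,
        {model.biomass_reaction_id: (biomass_value - 1e-9,
                                     biomass_value + 1e-9)})
    reversible = [j for j in range(len(rxns)) if lo[j] < 0 < hi[j]]
    if len(reversible) > 12:
        raise ValueError("too many reversible reactions for enumeration")
    best = np.inf
    for signs in product((-1, 1), repeat=len(reversible)):
        l2, h2 = lo.copy(), hi.copy()
        for j, s in zip(reversible, signs):
            if s > 0:
                l2[j] = 0.0
            else:
                h2[j] = 0.0
        for v in enumerate_vertices(S, l2, h2):
            best = min(best, float(np.sum(np.abs(v))))
    if not np.isfinite(best):
        raise ValueError("infeasible at fixed biomass")
    return best


# ---------------------------------------------------------------------------
# naive NG86


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def ng86_bruteforce(a: str, b: str) -> tuple[float | None, float | None]:
    """(dN, dS) by naive per-codon enumeration with Biopython translation.

    Conventions match the engine: three sites per codon with stop-creating
    changes nonsynonymous; pathways through intermediate stops discarded
    (all pathways kept if every one is blocked, stop steps nonsynonymous);
    Jukes-Cantor correction, None when saturated.
    """
    import math

    assert len(a) == len(b) and len(a) % 3 == 0
    S = Fraction(0)
    Sd = Fraction(0)
    Nd = Fraction(0)
    ncod = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3].upper(), b[i:i + 3].upper()
        if set(ca + cb) - set("ACGT"):
            continue
        if _aa(ca) == "*" or _aa(cb) == "*":
            continue
        ncod += 1
        for c in (ca, cb):
            syn = sum(
                1
                for pos in range(3) for nt in "ACGT"
                if nt != c[pos]
                and _aa(c[:pos] + nt + c[pos + 1:]) == _aa(c)
                and _aa(c[:pos] + nt + c[pos + 1:]) != "*")
            S += Fraction(syn, 3) / 2
        diff = [p for p in range(3) if ca[p] != cb[p]]
        if diff:
            paths = []
            for order in permutations(diff):
                cur = ca
                steps = []
                blocked = False
                for p in order:
                    nxt = cur[:p] + cb[p] + cur[p + 1:]
                    steps.append((cur, nxt))
                    if _aa(nxt) == "*" and nxt != cb:
                        blocked = True
                    cur = nxt
                paths.append((blocked, steps))
            usable = [st for bl, st in paths if not bl] or \
                     [st for _, st in paths]
            s_add = Fraction(0)
            n_add = Fraction(0)
            for steps in usable:
                for x, y in steps:
                    if _aa(x) != "*" and _aa(y) != "*" and _aa(x) == _aa(y):
                        s_add += 1
                    else:
                        n_add += 1
            Sd += s_add / len(usable)
            Nd += n_add / len(usable)
    if ncod == 0:
        return None, None
    N = 3 * ncod - S

    def jc(p):
        p = float(p)
        return None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    pS = Sd / S if S > 0 else Fraction(0)
    pN = Nd / N if N > 0 else Fraction(0)
    return jc(pN), jc(pS)
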