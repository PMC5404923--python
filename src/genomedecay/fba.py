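"""Six-step flux-balance procedure for minimal media and reaction classes.

Given a stoichiometric model, the analysis (i) checks growth on the
complete medium and sets a nonzero biomass floor, (ii) finds a
provably-minimal set of external nutrients supporting that floor (exact
MILP over binary uptake indicators), (iii) restricts exchanges to the
minimal medium, (iv) minimizes and maximizes every reaction flux (FVA),
classifying each reaction as essential (strictly signed flux range),
nonfunctional (only zero flux) or functional (zero and nonzero flux),
(v) maximizes and fixes biomass on the minimal medium, and (vi) minimizes
total absolute flux (parsimonious FBA) to obtain a loop-free flux profile.

Exchange convention: negative exchange flux is uptake.  Applying a medium
sets the exchange lower bound to ``-uptake_limit`` for medium nutrients and
``0`` otherwise; secretion keeps the reaction's stored upper bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from . import _lp
from .model import Medium, StoichiometricModel

#: feasibility tolerance on returned optima (|S v| residuals, bound slack)
EPS_FEAS = 1e-7
#: zero-flux tolerance used in reaction classification, model flux units
EPS_FLUX = 1e-6
#: biomass floor as a fraction of maximum biomass on the complete medium
DEFAULT_GROWTH_FLOOR_FRACTION = 0.1


class FbaError(RuntimeError):
    pass


class InfeasibleError(FbaError):
    pass


class UnboundedError(FbaError):
    pass


class AuxotrophicError(FbaError):
    """The model cannot produce biomass even on the complete medium."""


class ReactionClass(str, Enum):
    ESSENTIAL = "essential"
    FUNCTIONAL = "functional"
    NONFUNCTIONAL = "nonfunctional"


@dataclass(frozen=True)
class FluxState:
    fluxes: dict[str, float]
    objective_value: float
    status: str  # "optimal" | "infeasible"


@dataclass(frozen=True)
class MediumPrediction:
    medium: Medium
    achieved_biomass: float


@dataclass
class ModelAnalysis:
    genome_id: str
    grows_on_complete: bool
    max_biomass_complete: float
    growth_floor: float
    minimal_medium: Medium
    max_biomass_minimal: float
    fva_ranges: dict[str, tuple[float, float]]
    classes: dict[str, ReactionClass]
    parsimonious: FluxState

    def class_counts(self) -> dict[str, int]:
        out = {c.value: 0 for c in ReactionClass}
        for c in self.classes.values():
            out[c.value] += 1
        return out


class _System:
    """Model compiled to arrays, with a medium applied to exchange bounds."""

    def __init__(self, model: StoichiometricModel, medium: Medium):
        self.model = model
        S, mets, rxns = model.stoichiometric_matrix()
        self.S, self.met_ids, self.rxn_ids = S, mets, rxns
        self.index = {r: j for j, r in enumerate(rxns)}
        lo, hi = [], []
        for rid in rxns:
            r = model.reactions[rid]
            if r.is_exchange:
                met = r.exchanged_metabolite
                lo.append(-medium.uptake_limit if met in medium.nutrients
                          else 0.0)
                hi.append(r.upper_bound)
            else:
                lo.append(r.lower_bound)
                hi.append(r.upper_bound)
        self.lo = np.array(lo)
        self.hi = np.array(hi)
        self.biomass_j = self.index[model.biomass_reaction_id]
        self.exchange_js = {
            model.reactions[r].exchanged_metabolite: self.index[r]
            for r in rxns if model.reactions[r].is_exchange
        }

    def bounds(self, overrides: dict[str, tuple[float, float]] | None = None):
        lo, hi = self.lo.copy(), self.hi.copy()
        for rid, (a, b) in (overrides or {}).items():
            j = self.index[rid]
            lo[j] = max(lo[j], a)
            hi[j] = min(hi[j], b)
        return lo, hi

    def optimize(self, objective: dict[str, float], sense: str = "max",
                 overrides=None) -> tuple[str, np.ndarray | None, float | None]:
        c = np.zeros(len(self.rxn_ids))
        for rid, w in objective.items():
            c[self.index[rid]] = w
        if sense == "max":
            c = -c
        lo, hi = self.bounds(overrides)
        status, x, fun = _lp.solve_lp(
            c, A_eq=self.S, b_eq=np.zeros(self.S.shape[0]),
            bounds=list(zip(lo, hi)))
        if status == _lp.OPTIMAL:
            return status, x, (-fun if sense == "max" else fun)
        return status, None, None

    def flux_dict(self, x: np.ndarray) -> dict[str, float]:
        return {r: float(x[j]) for j, r in enumerate(self.rxn_ids)}


def _check_medium(model: StoichiometricModel, medium: Medium) -> None:
    unknown = medium.nutrients - model.exchangeable_metabolites
    if unknown:
        raise FbaError(
            f"medium nutrients not exchangeable in model "
            f"{model.genome_id!r}: {sorted(unknown)}")


def complete_medium(model: StoichiometricModel,
                    uptake_limit: float = 10.0) -> Medium:
    """Medium opening every exchange reaction of the model."""
    return Medium(nutrients=model.exchangeable_metabolites,
                  uptake_limit=uptake_limit)


def maximize_biomass(model: StoichiometricModel, medium: Medium) -> FluxState:
    """LP maximum of biomass flux under S v = 0, bounds and the medium."""
    _check_medium(model, medium)
    sys = _System(model, medium)
    status, x, obj = sys.optimize({model.biomass_reaction_id: 1.0})
    if status == _lp.UNBOUNDED:
        raise UnboundedError(
            "biomass objective unbounded; missing exchange constraint")
    if status == _lp.INFEASIBLE:
        return FluxState(fluxes={}, objective_value=float("nan"),
                         status="infeasible")
    return FluxState(fluxes=sys.flux_dict(x), objective_value=float(obj),
                     status="optimal")


def find_minimal_media(model: StoichiometricModel, growth_floor: float,
                       uptake_limit: float = 10.0) -> MediumPrediction:
    """Provably minimum-cardinality nutrient set sustaining the growth floor.

    Exact MILP with one binary uptake indicator per exchange reaction; ties
    among equal-cardinality optima are broken toward the lexicographically
    smallest nutrient-id set by a greedy sequence of fixed-cardinality
    feasibility MILPs.
    """
    full = complete_medium(model, uptake_limit)
    base = maximize_biomass(model, full)
    if base.status != "optimal" or base.objective_value < growth_floor - EPS_FEAS:
        raise AuxotrophicError(
            f"model {model.genome_id!r} is auxotrophic for biomass under "
            "complete medium (candidate for gapfilling)")

    sys = _System(model, full)
    nutrients = sorted(sys.exchange_js)  # candidate nutrient ids
    n, k = len(sys.rxn_ids), len(nutrients)

    def milp_setup(forced: set[str], cardinality: int | None):
        # variables: v (n floats) then y (k binaries)
        c = np.concatenate([np.zeros(n), np.ones(k)])
        A_eq = np.hstack([sys.S, np.zeros((sys.S.shape[0], k))])
        b_eq = np.zeros(sys.S.shape[0])
        rows, rhs = [], []
        # uptake allowed only when indicator on: v_ex + U*y >= 0
        for i, met in enumerate(nutrients):
            row = np.zeros(n + k)
            row[sys.exchange_js[met]] = -1.0
            row[n + i] = -uptake_limit
            rows.append(row)          # -v_ex - U y <= 0
            rhs.append(0.0)
        A_ub = np.array(rows)
        lo, hi = sys.bounds({model.biomass_reaction_id:
                             (growth_floor, np.inf)})
        bounds = list(zip(lo, hi))
        for met in nutrients:
            bounds.append((1.0, 1.0) if met in forced else (0.0, 1.0))
        if cardinality is not None:
            row = np.concatenate([np.zeros(n), np.ones(k)])
            A_eq = np.vstack([A_eq, row])
            b_eq = np.append(b_eq, float(cardinality))
        integrality = np.concatenate([np.zeros(n), np.ones(k)])
        return c, integrality, A_eq, b_eq, A_ub, np.array(rhs), bounds

    c, integ, A_eq, b_eq, A_ub, b_ub, bounds = milp_setup(set(), None)
    status, x, fun = _lp.solve_milp(c, integ, A_eq, b_eq, A_ub, b_ub, bounds)
    if status != _lp.OPTIMAL:
        raise InfeasibleError("minimal-media MILP infeasible")
    k_opt = int(round(fun))

    forced: set[str] = set()
    for met in nutrients:
        if len(forced) == k_opt:
            break
        trial = forced | {met}
        c, integ, A_eq, b_eq, A_ub, b_ub, bounds = milp_setup(trial, k_opt)
        status, _, _ = _lp.solve_milp(c, integ, A_eq, b_eq, A_ub, b_ub, bounds)
        if status == _lp.OPTIMAL:
            forced = trial
    assert len(forced) == k_opt

    medium = Medium(nutrients=frozenset(forced), uptake_limit=uptake_limit)
    achieved = maximize_biomass(model, medium)
    return MediumPrediction(medium=medium,
                            achieved_biomass=achieved.objective_value)


def flux_variability(
    model: StoichiometricModel,
    medium: Medium,
    fixed: dict[str, tuple[float, float]] | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-reaction LP flux minima and maxima under the medium and
    additional fixed flux intervals (e.g. a biomass floor)."""
    _check_medium(model, medium)
    sys = _System(model, medium)
    out: dict[str, tuple[float, float]] = {}
    for rid in sys.rxn_ids:
        st_lo, _, lo = sys.optimize({rid: 1.0}, sense="min", overrides=fixed)
        st_hi, _, hi = sys.optimize({rid: 1.0}, sense="max", overrides=fixed)
        if st_lo != _lp.OPTIMAL or st_hi != _lp.OPTIMAL:
            raise InfeasibleError(
                f"FVA base problem infeasible (reaction {rid!r})")
        out[rid] = (float(lo), float(hi))
    return out


def classify_reactions(
    fva_ranges: dict[str, tuple[float, float]],
    epsilon: float = EPS_FLUX,
) -> dict[str, ReactionClass]:
    """Essential iff the flux range is strictly signed; nonfunctional iff
    only zero flux is attainable; functional otherwise."""
    out = {}
    for rid, (lo, hi) in fva_ranges.items():
        if lo > epsilon or hi < -epsilon:
            out[rid] = ReactionClass.ESSENTIAL
        elif abs(lo) <= epsilon and abs(hi) <= epsilon:
            out[rid] = ReactionClass.NONFUNCTIONAL
        else:
            out[rid] = ReactionClass.FUNCTIONAL
    return out


def parsimonious_flux(model: StoichiometricModel, medium: Medium,
                      biomass_value: float | None = None) -> FluxState:
    """Fix biomass at its maximum, then minimize total absolute flux.

    Implemented by standard flux splitting (v = p - n with p, n >= 0,
    minimizing sum p + n), which drives every futile cycle to zero flux.
    """
    _check_medium(model, medium)
    if biomass_value is None:
        fs = maximize_biomass(model, medium)
        if fs.status != "optimal":
            raise InfeasibleError("parsimonious FBA: base problem infeasible")
        biomass_value = fs.objective_value
    sys = _System(model, medium)
    n = len(sys.rxn_ids)
    lo, hi = sys.bounds({model.biomass_reaction_id:
                         (biomass_value - 1e-9, biomass_value + 1e-9)})
    # variables [p; q], v = p - q
    A_eq = np.hstack([sys.S, -sys.S])
    b_eq = np.zeros(sys.S.shape[0])
    # v bounds become linear constraints lo <= p - q <= hi
    I = np.eye(n)
    A_ub = np.vstack([np.hstack([I, -I]), np.hstack([-I, I])])
    b_ub = np.concatenate([hi, -lo])
    bounds = [(0.0, max(0.0, h)) for h in hi] + \
             [(0.0, max(0.0, -l)) for l in lo]
    c = np.ones(2 * n)
    status, x, _ = _lp.solve_lp(c, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub,
                                bounds=bounds)
    if status != _lp.OPTIMAL:
        raise InfeasibleError("parsimonious FBA infeasible at fixed biomass")
    v = x[:n] - x[n:]
    fluxes = {r: float(v[j]) for j, r in enumerate(sys.rxn_ids)}
    return FluxState(fluxes=fluxes,
                     objective_value=fluxes[model.biomass_reaction_id],
                     status="optimal")


def six_step_analysis(
    model: StoichiometricModel,
    uptake_limit: float = 10.0,
    growth_floor_fraction: float = DEFAULT_GROWTH_FLOOR_FRACTION,
    epsilon: float = EPS_FLUX,
    fix_biomass_at: str = "floor",
) -> ModelAnalysis:
    """Run the full six-step procedure on one model.

    ``fix_biomass_at`` chooses the biomass constraint during classification:
    ``"floor"`` (biomass >= growth floor, the default reading) or ``"max"``
    (biomass fixed at its minimal-medium maximum).
    """
    if fix_biomass_at not in ("floor", "max"):
        raise ValueError("fix_biomass_at must be 'floor' or 'max'")
    full = complete_medium(model, uptake_limit)

    def step(i, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except FbaError as exc:
            raise type(exc)(f"six-step analysis, step ({i}): {exc}") from exc

    # (i) nonzero biomass floor from growth on the complete medium
    base = step("i", maximize_biomass, model, full)
    grows = base.status == "optimal" and base.objective_value > epsilon
    if not grows:
        raise AuxotrophicError(
            f"six-step analysis, step (i): model {model.genome_id!r} is "
            "auxotrophic for biomass under complete medium")
    floor = growth_floor_fraction * base.objective_value

    # (ii) minimal medium
    pred = step("ii", find_minimal_media, model, floor, uptake_limit)

    # (v) maximum biomass on the minimal medium (needed before iv if
    # classification fixes biomass at its maximum)
    vmax = step("v", maximize_biomass, model, pred.medium).objective_value

    # (iii)+(iv) FVA with exchanges restricted to the minimal medium
    target = floor if fix_biomass_at == "floor" else vmax - 1e-9
    fva = step("iv", flux_variability, model, pred.medium,
               {model.biomass_reaction_id: (target, np.inf)})
    classes = classify_reactions(fva, epsilon)

    # (vi) parsimonious flux profile at maximum biomass
    pars = step("vi", parsimonious_flux, model, pred.medium, vmax)

    return ModelAnalysis(
        genome_id=model.genome_id,
        grows_on_complete=grows,
        max_biomass_complete=base.objective_value,
        growth_floor=floor,
        minimal_medium=pred.medium,
        max_biomass_minimal=vmax,
        fva_ranges=fva,
        classes=classes,
        parsimonious=pars,
    )


def analysis_to_dict(analysis: ModelAnalysis) -> dict:
    """JSON-serializable summary of a six-step analysis."""
    return {
        "genome_id": analysis.genome_id,
        "grows_on_complete": analysis.grows_on_complete,
        "max_biomass_complete": analysis.max_biomass_complete,
        "growth_floor": analysis.growth_floor,
        "minimal_medium": sorted(analysis.minimal_medium.nutrients),
        "uptake_limit": analysis.minimal_medium.uptake_limit,
        "max_biomass_minimal": analysis.max_biomass_minimal,
        "fva_ranges": {r: list(v) for r, v in sorted(analysis.fva_ranges.items())},
        "classes": {r: c.value for r, c in sorted(analysis.classes.items())},
        "class_counts": analysis.class_counts(),
        "parsimonious_fluxes": dict(sorted(analysis.parsimonious.fluxes.items())),
    }
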