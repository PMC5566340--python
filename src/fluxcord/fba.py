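"""Flux balance analysis: parsimonious point solutions and flux variability.

Given a model and a scenario (medium + objective), the engine solves the
standard FBA linear program

    optimize  c·v   subject to   S·v = 0,  lb <= v <= ub,

then, at the optimum, minimizes total absolute flux Σ|v| (parsimonious
FBA) so that the reported flux profile is a unique, cycle-free
representative of the optimal face.  Reactions are called active when
|v| exceeds a small flux threshold on that parsimonious solution.

Flux variability analysis (per-reaction min/max flux at a fraction of
the optimum) is provided as a diagnostic for alternative optima; it does
not enter the activity calls by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model_core import MetabolicModel, Scenario

__all__ = [
    "FluxProfile",
    "FbaError",
    "ScenarioInfeasibleError",
    "UnboundedObjectiveError",
    "solve_fba",
    "flux_variability",
    "call_active",
    "DEFAULT_FLUX_TOL",
]

DEFAULT_FLUX_TOL = 1e-6
_SOLVER_OPTS = {"presolve": True}
# relative slack when pinning the objective for the parsimony / FVA stage
_OPT_SLACK = 1e-9


class FbaError(RuntimeError):
    pass


class ScenarioInfeasibleError(FbaError):
    """The scenario's bounds admit no steady-state flux distribution."""


class UnboundedObjectiveError(FbaError):
    """The objective can be improved without limit under the given bounds."""


@dataclass
class FluxProfile:
    """One parsimonious flux solution plus activity calls for (model, scenario)."""

    model_id: str
    scenario_name: str
    objective_value: float
    fluxes: dict[str, float]
    active: dict[str, bool] = field(default_factory=dict)
    flux_ranges: dict[str, tuple[float, float]] | None = None


def _build_lp(model: MetabolicModel, scenario: Scenario):
    """Stoichiometric matrix, bounds (scenario-overridden) and objective vector."""
    scenario.validate_against(model)
    rxn_ids = list(model.reactions)
    met_ids = list(model.metabolites)
    met_index = {m: i for i, m in enumerate(met_ids)}

    rows, cols, vals = [], [], []
    for j, rid in enumerate(rxn_ids):
        for met, coef in model.reactions[rid].stoichiometry.items():
            rows.append(met_index[met])
            cols.append(j)
            vals.append(coef)
    S = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids))
    )

    bounds = []
    for rid in rxn_ids:
        r = model.reactions[rid]
        lo, hi = r.lower_bound, r.upper_bound
        if rid in scenario.exchange_bounds:
            lo, hi = scenario.exchange_bounds[rid]
        bounds.append((lo, hi))

    c = np.zeros(len(rxn_ids))
    for rid, w in scenario.objective.items():
        c[rxn_ids.index(rid)] = w
    return S, bounds, c, rxn_ids


def _raise_for_status(res, scenario: Scenario, bounds, rxn_ids) -> None:
    if res.status == 2:
        pinned = {
            rid: bounds[rxn_ids.index(rid)] for rid in scenario.exchange_bounds
        }
        raise ScenarioInfeasibleError(
            f"scenario {scenario.name!r} infeasible under exchange bounds {pinned}"
        )
    if res.status == 3:
        raise UnboundedObjectiveError(
            f"scenario {scenario.name!r}: objective on "
            f"{sorted(scenario.objective)} is unbounded"
        )
    if res.status != 0:
        raise FbaError(f"scenario {scenario.name!r}: solver failure: {res.message}")


def solve_fba(
    model: MetabolicModel,
    scenario: Scenario,
    tol: float = DEFAULT_FLUX_TOL,
    parsimonious: bool = True,
) -> FluxProfile:
    """Solve the scenario LP; return the parsimonious optimal flux profile.

    Parameters
    ----------
    tol
        Flux threshold for the active/inactive call (strict ``|v| > tol``).
    parsimonious
        When True (default), a second LP minimizes total absolute flux
        subject to the objective staying at its optimum, yielding a unique
        representative profile free of arbitrary flux loops.
    """
    S, bounds, c, rxn_ids = _build_lp(model, scenario)
    sign = -1.0 if scenario.sense == "maximize" else 1.0

    res = linprog(
        sign * c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
        method="highs", options=_SOLVER_OPTS,
    )
    _raise_for_status(res, scenario, bounds, rxn_ids)
    opt = float(c @ res.x)
    v = res.x

    if parsimonious:
        v = _minimize_total_flux(S, bounds, c, opt, scenario)

    fluxes = {rid: float(v[j]) for j, rid in enumerate(rxn_ids)}
    profile = FluxProfile(
        model_id=model.species_name,
        scenario_name=scenario.name,
        objective_value=opt,
        fluxes=fluxes,
    )
    profile.active = call_active(profile, tol)
    return profile


def _minimize_total_flux(S, bounds, c, opt, scenario: Scenario) -> np.ndarray:
    """min Σ t  s.t.  S v = 0,  -t <= v <= t,  objective pinned at ``opt``."""
    n = S.shape[1]
    # variables [v, t]; the objective is pinned by an exact equality row
    A_eq = sparse.vstack(
        [
            sparse.hstack([S, sparse.csr_matrix(S.shape)]),
            sparse.hstack([sparse.csr_matrix(c), sparse.csr_matrix((1, n))]),
        ]
    )
    b_eq = np.concatenate([np.zeros(S.shape[0]), [opt]])
    eye = sparse.eye(n)
    A_ub = sparse.vstack(
        [
            sparse.hstack([eye, -eye]),   # v - t <= 0
            sparse.hstack([-eye, -eye]),  # -v - t <= 0
        ]
    )
    b_ub = np.zeros(2 * n)

    cost = np.concatenate([np.zeros(n), np.ones(n)])
    lp_bounds = list(bounds) + [(0, None)] * n
    res = linprog(
        cost, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
        bounds=lp_bounds, method="highs", options=_SOLVER_OPTS,
    )
    if res.status != 0:  # the pinned problem contains the stage-1 solution
        raise FbaError(
            f"scenario {scenario.name!r}: parsimony stage failed: {res.message}"
        )
    return res.x[:n]


def flux_variability(
    model: MetabolicModel,
    scenario: Scenario,
    gamma: float = 1.0,
) -> dict[str, tuple[float, float]]:
    """Per-reaction (min, max) flux with the objective held at ``gamma`` × optimum.

    ``gamma`` = 1 probes alternative optima; ``gamma`` = 0 explores the whole
    feasible space.  Used as a diagnostic for whether a single flux profile
    is the only plausible one.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    S, bounds, c, rxn_ids = _build_lp(model, scenario)
    sign = -1.0 if scenario.sense == "maximize" else 1.0
    res = linprog(
        sign * c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
        method="highs", options=_SOLVER_OPTS,
    )
    _raise_for_status(res, scenario, bounds, rxn_ids)
    opt = float(c @ res.x)

    # hold the objective at a gamma-fraction of its optimal value
    if scenario.sense == "maximize":
        target = gamma * opt if opt >= 0 else opt / max(gamma, _OPT_SLACK)
        row, rhs = -c, -(target - _OPT_SLACK * max(1.0, abs(opt)))
    else:
        target = gamma * opt if opt <= 0 else opt / max(gamma, _OPT_SLACK)
        row, rhs = c, target + _OPT_SLACK * max(1.0, abs(opt))
    A_ub = sparse.csr_matrix(row)
    b_ub = np.array([rhs])

    ranges: dict[str, tuple[float, float]] = {}
    n = len(rxn_ids)
    for j, rid in enumerate(rxn_ids):
        obj = np.zeros(n)
        obj[j] = 1.0
        lo = linprog(obj, A_ub=A_ub, b_ub=b_ub, A_eq=S, b_eq=np.zeros(S.shape[0]),
                     bounds=bounds, method="highs", options=_SOLVER_OPTS)
        hi = linprog(-obj, A_ub=A_ub, b_ub=b_ub, A_eq=S, b_eq=np.zeros(S.shape[0]),
                     bounds=bounds, method="highs", options=_SOLVER_OPTS)
        _raise_for_status(lo, scenario, bounds, rxn_ids)
        _raise_for_status(hi, scenario, bounds, rxn_ids)
        ranges[rid] = (float(lo.x[j]), float(hi.x[j]))
    return ranges


def call_active(profile: FluxProfile, tol: float = DEFAULT_FLUX_TOL) -> dict[str, bool]:
    """Activity calls: strictly ``|flux| > tol`` on the point solution.

    Gene/gapfill filtering is applied downstream in concordance scoring so
    gapfilled reactions remain countable as their own category.
    """
    if tol < 0:
        raise ValueError(f"flux threshold must be >= 0, got {tol}")
    return {rid: abs(v) > tol for rid, v in profile.fluxes.items()}


def call_active_anyopt(
    model: MetabolicModel,
    scenario: Scenario,
    tol: float = DEFAULT_FLUX_TOL,
) -> dict[str, bool]:
    """Alternative-optima activity rule: active if any optimal solution uses the reaction."""
    if tol < 0:
        raise ValueError(f"flux threshold must be >= 0, got {tol}")
    ranges = flux_variability(model, scenario, gamma=1.0)
    return {rid: max(abs(lo), abs(hi)) > tol for rid, (lo, hi) in ranges.items()}
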