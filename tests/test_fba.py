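"""FBA engine: analytic optima, parsimony vs. exhaustive enumeration, FVA, errors."""

import itertools
import math

import numpy as np
import pytest

from fluxcord import (
    FluxProfile,
    Reaction,
    Scenario,
    ScenarioInfeasibleError,
    UnboundedObjectiveError,
    call_active,
    flux_variability,
    solve_fba,
)
from fluxcord.fba import _build_lp

from conftest import build_model


# ---------------------------------------------------------------------------
# independent oracle: exhaustive enumeration of arrangement vertices
# ---------------------------------------------------------------------------


def brute_force_min_abs_flux(model, scenario, opt):
    """Minimum Σ|v| over the optimal face, by exhaustive vertex enumeration.

    The minimum of the piecewise-linear convex Σ|v| over the polytope
    {S·v = 0, c·v = opt, lb <= v <= ub} is attained where enough of the
    constraints {v_i = lb_i, v_i = ub_i, v_i = 0} are tight to pin a
    vertex of the arrangement; enumerate all such candidate points.
    """
    S, bounds, c, _ = _build_lp(model, scenario)
    S = S.toarray()
    A = np.vstack([S, c])
    b = np.concatenate([np.zeros(S.shape[0]), [opt]])
    n = A.shape[1]
    k = n - np.linalg.matrix_rank(A)
    best = math.inf
    for fixed_vars in itertools.combinations(range(n), k):
        choices = [
            {bounds[i][0], bounds[i][1], 0.0} - {None, math.inf, -math.inf}
            for i in fixed_vars
        ]
        for vals in itertools.product(*choices):
            rest = [i for i in range(n) if i not in fixed_vars]
            Ar = A[:, rest]
            br = b - (A[:, list(fixed_vars)] @ np.array(vals) if fixed_vars else 0.0)
            sol, *_ = np.linalg.lstsq(Ar, br, rcond=None)
            v = np.zeros(n)
            v[rest] = sol
            for i, val in zip(fixed_vars, vals):
                v[i] = val
            if np.max(np.abs(A @ v - b)) > 1e-7:
                continue
            if any(v[i] < bounds[i][0] - 1e-9 or v[i] > bounds[i][1] + 1e-9 for i in range(n)):
                continue
            best = min(best, float(np.abs(v).sum()))
    return best


def total_abs_flux(profile):
    return sum(abs(v) for v in profile.fluxes.values())


def assert_mass_balanced(model, profile, tol=1e-8):
    for mid in model.metabolites:
        net = sum(
            coef * profile.fluxes[rid]
            for rid, rxn in model.reactions.items()
            for m, coef in rxn.stoichiometry.items()
            if m == mid
        )
        assert abs(net) <= tol, f"metabolite {mid} imbalance {net}"


# ---------------------------------------------------------------------------
# analytic optima
# ---------------------------------------------------------------------------


def test_chain_bound_limited_optimum(chain_model):
    model, scenario = chain_model
    profile = solve_fba(model, scenario)
    assert profile.objective_value == pytest.approx(10.0, rel=1e-9)
    assert profile.fluxes["EX_A"] == pytest.approx(-10.0, rel=1e-9)
    assert profile.fluxes["CONV"] == pytest.approx(10.0, rel=1e-9)
    assert profile.fluxes["EX_B"] == pytest.approx(10.0, rel=1e-9)
    assert all(profile.active.values())
    assert_mass_balanced(model, profile)


def test_chain_closed_uptake_all_zero(chain_model):
    model, _ = chain_model
    closed = Scenario("closed", exchange_bounds={"EX_A": (0, 0)}, objective={"EX_B": 1})
    profile = solve_fba(model, closed)
    assert profile.objective_value == pytest.approx(0.0, abs=1e-12)
    assert all(abs(v) <= 1e-12 for v in profile.fluxes.values())
    assert not any(profile.active.values())


def test_parallel_parsimony_routes_single_branch(parallel_model):
    model, scenario = parallel_model
    profile = solve_fba(model, scenario)
    assert profile.objective_value == pytest.approx(10.0, rel=1e-9)
    # the two-step detour is left idle
    assert abs(profile.fluxes["LONG1"]) <= 1e-9
    assert abs(profile.fluxes["LONG2"]) <= 1e-9
    assert profile.fluxes["DIRECT"] == pytest.approx(10.0, rel=1e-9)
    oracle = brute_force_min_abs_flux(model, scenario, profile.objective_value)
    assert total_abs_flux(profile) == pytest.approx(oracle, rel=1e-7)


def test_futile_cycle_suppressed_by_parsimony(futile_model):
    model, scenario = futile_model
    loose = solve_fba(model, scenario, parsimonious=False)
    profile = solve_fba(model, scenario)
    assert profile.objective_value == pytest.approx(loose.objective_value, rel=1e-9)
    assert abs(profile.fluxes["CYC1"]) <= 1e-9
    assert abs(profile.fluxes["CYC2"]) <= 1e-9
    oracle = brute_force_min_abs_flux(model, scenario, profile.objective_value)
    assert total_abs_flux(profile) == pytest.approx(oracle, rel=1e-7)


# ---------------------------------------------------------------------------
# flux variability
# ---------------------------------------------------------------------------


def test_fva_chain_no_slack_at_gamma_1(chain_model):
    model, scenario = chain_model
    ranges = flux_variability(model, scenario, gamma=1.0)
    for rid, (lo, hi) in ranges.items():
        assert lo == pytest.approx(hi, abs=1e-7), rid
        assert abs(lo) == pytest.approx(10.0, rel=1e-7), rid


def test_fva_parallel_branches_swing_full_range(parallel_model):
    model, scenario = parallel_model
    ranges = flux_variability(model, scenario, gamma=1.0)
    for rid in ("DIRECT", "LONG1", "LONG2"):
        lo, hi = ranges[rid]
        assert lo == pytest.approx(0.0, abs=1e-7)
        assert hi == pytest.approx(10.0, rel=1e-7)
    # the shared trunk has no freedom
    assert ranges["EX_B"][0] == pytest.approx(10.0, rel=1e-7)


def test_fva_gamma_zero_releases_objective(chain_model):
    model, scenario = chain_model
    ranges = flux_variability(model, scenario, gamma=0.0)
    assert ranges["EX_B"][0] == pytest.approx(0.0, abs=1e-7)
    assert ranges["EX_B"][1] == pytest.approx(10.0, rel=1e-7)


def test_fva_rejects_bad_gamma(chain_model):
    model, scenario = chain_model
    with pytest.raises(ValueError, match="gamma"):
        flux_variability(model, scenario, gamma=1.5)


# ---------------------------------------------------------------------------
# activity calls and error contracts
# ---------------------------------------------------------------------------


def test_active_call_boundary_is_strict():
    profile = FluxProfile("m", "s", 0.0, {"r1": 1e-6, "r2": 1.0000001e-6, "r3": 0.0})
    active = call_active(profile, tol=1e-6)
    assert active == {"r1": False, "r2": True, "r3": False}
    with pytest.raises(ValueError, match=">= 0"):
        call_active(profile, tol=-1)


def test_infeasible_scenario_error(chain_model):
    model, _ = chain_model
    # forced export with uptake shut
    bad = Scenario(
        "impossible", exchange_bounds={"EX_A": (0, 0), "EX_B": (5, 10)},
        objective={"EX_B": 1},
    )
    with pytest.raises(ScenarioInfeasibleError, match="impossible"):
        solve_fba(model, bad)


def test_unbounded_objective_error():
    model = build_model(
        "unbounded",
        [("A[e]", "e"), ("B[e]", "e")],
        [
            Reaction("EX_A", {"A[e]": -1}, -math.inf, 0),
            Reaction("CONV", {"A[e]": -1, "B[e]": 1}, 0, math.inf),
            Reaction("EX_B", {"B[e]": -1}, 0, math.inf),
        ],
    )
    scenario = Scenario("runaway", objective={"EX_B": 1})
    with pytest.raises(UnboundedObjectiveError, match="unbounded"):
        solve_fba(model, scenario)


def test_objective_monotone_in_uptake_allowance(chain_model):
    model, _ = chain_model
    prev = -1.0
    for uptake in (0, 2, 5, 10, 50):
        scen = Scenario("s", exchange_bounds={"EX_A": (-uptake, 0)}, objective={"EX_B": 1})
        obj = solve_fba(model, scen).objective_value
        assert obj >= prev - 1e-9
        prev = obj


def test_refixing_profile_reproduces_objective(parallel_model):
    model, scenario = parallel_model
    profile = solve_fba(model, scenario)
    pinned = build_model(
        "pinned",
        [(m.id, m.compartment) for m in model.metabolites.values()],
        [
            Reaction(r.id, r.stoichiometry,
                     profile.fluxes[r.id] - 1e-9, profile.fluxes[r.id] + 1e-9)
            for r in model.reactions.values()
        ],
    )
    re_solved = solve_fba(pinned, Scenario("re", objective={"EX_B": 1}), parsimonious=False)
    assert re_solved.objective_value == pytest.approx(profile.objective_value, rel=1e-9)


def test_scenario_separation_on_two_mode_species(trio):
    """The CO2-reduction scenario runs the fixation branch with zero acetate uptake,
    and the acetate-oxidation scenario does the converse."""
    _, builds = trio
    two_mode = next(b for b in builds if len(b.scenarios) == 2 and "RTCA_1" in b.model.reactions)
    by_name = {s.name: s for s in two_mode.scenarios}
    reduce_profile = solve_fba(two_mode.model, by_name["reduction_of_co2"])
    oxidize_profile = solve_fba(two_mode.model, by_name["oxidation_of_acetate"])
    assert reduce_profile.active["RTCA_1"] and not reduce_profile.active["AOX_1"]
    assert abs(reduce_profile.fluxes["EX_ac"]) <= 1e-9
    assert oxidize_profile.active["AOX_1"] and not oxidize_profile.active["RTCA_1"]
    assert abs(oxidize_profile.fluxes["EX_h2"]) <= 1e-9


# ---------------------------------------------------------------------------
# cross-check against an independent FBA implementation
# ---------------------------------------------------------------------------


def to_cobra(model, scenario):
    cobra = pytest.importorskip("cobra")
    cm = cobra.Model(model.species_name)
    mets = {
        m.id: cobra.Metabolite(m.id.replace("[", "_").rstrip("]"), compartment=m.compartment)
        for m in model.metabolites.values()
    }
    rxns = []
    for r in model.reactions.values():
        cr = cobra.Reaction(r.id)
        cr.add_metabolites({mets[mid]: coef for mid, coef in r.stoichiometry.items()})
        lo, hi = r.lower_bound, r.upper_bound
        if r.id in scenario.exchange_bounds:
            lo, hi = scenario.exchange_bounds[r.id]
        cr.bounds = (lo, hi)
        rxns.append(cr)
    cm.add_reactions(rxns)
    cm.objective = {cm.reactions.get_by_id(rid): w for rid, w in scenario.objective.items()}
    return cm


@pytest.mark.parametrize("fixture_name", ["chain_model", "parallel_model", "futile_model"])
def test_matches_cobra_pfba(fixture_name, request):
    """Objective and total absolute flux agree with cobrapy's pFBA on toy networks."""
    from cobra.flux_analysis import pfba

    model, scenario = request.getfixturevalue(fixture_name)
    profile = solve_fba(model, scenario)
    cm = to_cobra(model, scenario)
    assert cm.optimize().objective_value == pytest.approx(profile.objective_value, abs=1e-6)
    cobra_sum_abs = pfba(cm).objective_value
    assert total_abs_flux(profile) == pytest.approx(cobra_sum_abs, abs=1e-5)


def test_generated_species_matches_cobra(trio):
    from cobra.flux_analysis import pfba

    _, builds = trio
    b = builds[0]
    scenario = b.scenarios[0]
    profile = solve_fba(b.model, scenario)
    cm = to_cobra(b.model, scenario)
    assert cm.optimize().objective_value == pytest.approx(profile.objective_value, abs=1e-6)
    assert total_abs_flux(profile) == pytest.approx(pfba(cm).objective_value, abs=1e-4)
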