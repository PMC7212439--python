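"""Optimum-contribution solvers against enumeration and a generic
constrained quadratic optimiser."""

import itertools

import numpy as np
import pytest
from scipy.optimize import LinearConstraint, minimize

from gocsim import OCSProblem, calibrate_omega, mating_plan, solve_continuous, solve_integer
from gocsim.ocs import objective_value


def _problem(gebv, G, sexes, w, t, rng_pd=None):
    return OCSProblem(
        gebv=np.asarray(gebv, float),
        G=np.asarray(G, float),
        sexes=np.asarray(sexes),
        penalty_weight=w,
        n_matings=t,
        offspring_per_mating=2,
    )


def _random_problem(rng, n_m=4, n_f=4, w=2.0, t=4):
    n = n_m + n_f
    A = rng.normal(size=(n, n + 3))
    G = A @ A.T / (n + 3)
    gebv = rng.normal(size=n)
    sexes = np.array(["M"] * n_m + ["F"] * n_f)
    return _problem(gebv, G, sexes, w, t)


def _enumerate_optimum(problem):
    """Brute force over all integer sire mating vectors and dam subsets."""
    t = problem.n_matings
    males, females = problem.males, problem.females
    best = (-np.inf, None, None)
    for cuts in itertools.combinations_with_replacement(range(males.size), t):
        m = np.zeros(males.size, dtype=np.int64)
        for c in cuts:
            m[c] += 1
        for dams in itertools.combinations(females, t):
            c = np.zeros(problem.gebv.size)
            c[males] = m / (2 * t)
            c[list(dams)] = 1 / (2 * t)
            u = objective_value(problem, c)
            if u > best[0]:
                best = (u, m, np.array(dams))
    return best


# ---------------------------------------------------------------------------
# continuous relaxation


def test_zero_penalty_puts_everything_on_best_candidates():
    p = _problem([3.0, 5.0, 1.0, 2.0], np.eye(4), ["M", "M", "F", "F"], 0.0, 2)
    c = solve_continuous(p)
    assert c[1] == pytest.approx(0.5) and c[3] == pytest.approx(0.5)
    assert c[0] == c[2] == 0.0


def test_equal_merit_identity_G_gives_uniform_contributions():
    p = _problem(np.ones(6), np.eye(6), ["M"] * 3 + ["F"] * 3, 5.0, 3)
    c = solve_continuous(p)
    assert np.allclose(c[:3], 1 / 6, atol=1e-8)
    assert np.allclose(c[3:], 1 / 6, atol=1e-8)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_continuous_matches_generic_qp_solver(seed):
    rng = np.random.default_rng(seed)
    p = _random_problem(rng)
    c_mine = solve_continuous(p)
    is_male = (p.sexes == "M").astype(float)
    cons = LinearConstraint(np.vstack([is_male, 1 - is_male]), [0.5, 0.5], [0.5, 0.5])
    res = minimize(
        lambda c: -(c @ p.gebv - p.penalty_weight * c @ p.G @ c),
        x0=np.full(8, 1 / 8),
        jac=lambda c: -(p.gebv - 2 * p.penalty_weight * (p.G @ c)),
        bounds=[(0, None)] * 8,
        constraints=[cons],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    assert res.success
    assert np.max(np.abs(c_mine - res.x)) < 1e-6
    assert objective_value(p, c_mine) >= objective_value(p, res.x) - 1e-9


# ---------------------------------------------------------------------------
# integer search


def test_three_matings_all_to_best_male():
    p = _problem([5.0, 1.0, 0.0, 0.0, 0.0], np.eye(5),
                 ["M", "M", "F", "F", "F"], 0.01, 3)
    sol = solve_integer(p, rng=0)
    assert sol.male_matings[0] == 3
    u, m, dams = _enumerate_optimum(p)
    assert sol.objective == pytest.approx(u, abs=1e-12)


@pytest.mark.parametrize("seed", [10, 11, 12])
def test_integer_matches_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    p = _random_problem(rng, n_m=4, n_f=5, w=1.5, t=3)
    sol = solve_integer(p, rng=seed)
    u, m, dams = _enumerate_optimum(p)
    assert sol.objective == pytest.approx(u, abs=1e-9)


def test_penalty_dominant_minimises_group_relationship():
    rng = np.random.default_rng(5)
    p = _random_problem(rng, n_m=3, n_f=4, w=1e4, t=2)
    sol = solve_integer(p, rng=5)
    u, m, dams = _enumerate_optimum(p)
    assert sol.objective == pytest.approx(u, abs=1e-6)
    # the chosen plan has the minimum c'Gc over all feasible plans
    best_quad = None
    t = p.n_matings
    for cuts in itertools.combinations_with_replacement(range(3), t):
        mm = np.zeros(3, dtype=np.int64)
        for c in cuts:
            mm[c] += 1
        for dd in itertools.combinations(p.females, t):
            c = np.zeros(7)
            c[p.males] = mm / (2 * t)
            c[list(dd)] = 1 / (2 * t)
            q = c @ p.G @ c
            best_quad = q if best_quad is None else min(best_quad, q)
    c_sol = sol.contributions
    assert c_sol @ p.G @ c_sol == pytest.approx(best_quad, rel=1e-3)


def test_integer_beats_rounded_continuous_and_truncation():
    rng = np.random.default_rng(6)
    p = _random_problem(rng, n_m=6, n_f=8, w=3.0, t=5)
    sol = solve_integer(p, rng=6)
    sol.validate()
    from gocsim.ocs import _round_matings, _truncation_plan

    cont = solve_continuous(p)
    m_r = _round_matings(cont[p.males], p.n_matings)
    from gocsim.ocs import _plan_objective, _seed_dams

    d_r = _seed_dams(p, cont, rng)
    assert sol.objective >= _plan_objective(p, m_r, d_r) - 1e-12
    m_t, d_t = _truncation_plan(p)
    assert sol.objective >= _plan_objective(p, m_t, d_t) - 1e-12


def test_integer_deterministic_given_seed():
    rng = np.random.default_rng(8)
    p = _random_problem(rng, n_m=5, n_f=7, w=2.0, t=4)
    a = solve_integer(p, rng=99)
    b = solve_integer(p, rng=99)
    assert a.objective == b.objective
    assert np.array_equal(a.male_matings, b.male_matings)
    assert np.array_equal(a.dam_indices, b.dam_indices)


def test_group_relationship_non_increasing_in_penalty():
    """On fixed candidate data the optimum's c'Gc falls as the penalty
    grows (checked exactly via enumeration-sized instances)."""
    rng = np.random.default_rng(9)
    p0 = _random_problem(rng, n_m=4, n_f=5, w=0.5, t=3)
    quads = []
    for w in (0.5, 2.0, 8.0, 32.0):
        p = _problem(p0.gebv, p0.G, p0.sexes, w, 3)
        u, m, dams = _enumerate_optimum(p)
        c = np.zeros(9)
        c[p.males] = m / 6
        c[dams] = 1 / 6
        quads.append(c @ p.G @ c)
    assert all(b <= a + 1e-12 for a, b in zip(quads, quads[1:]))


def test_infeasible_candidate_counts_rejected():
    p = _problem([1.0, 2.0], np.eye(2), ["M", "F"], 1.0, 2)
    with pytest.raises(ValueError, match="infeasible"):
        solve_integer(p, rng=0)


# ---------------------------------------------------------------------------
# mating plan


def test_mating_plan_counts_and_single_sire():
    p = _problem([1.0, 2.0] + [0.0] * 5, np.eye(7), ["M", "M"] + ["F"] * 5, 0.01, 5)
    sol = solve_integer(p, rng=1)
    pairs = mating_plan(sol, rng=1)
    assert len(pairs) == 5
    dams_used = [d for _, d in pairs]
    assert sorted(dams_used) == sorted(sol.dam_indices.tolist())  # each dam once
    counts = {}
    for s, _ in pairs:
        counts[s] = counts.get(s, 0) + 1
    for i in np.flatnonzero(sol.male_matings):
        assert counts[int(i)] == int(sol.male_matings[i])


# ---------------------------------------------------------------------------
# penalty calibration


def test_calibrate_omega_converges_on_synthetic_response():
    def runner(w, rep):
        rng = np.random.default_rng(1000 + rep)
        return 0.002 + 0.05 * 10.0 / (10.0 + w) + rng.normal(0, 2e-4)

    w, achieved, se = calibrate_omega(runner, 0.01, n_reps=4, tolerance=0.0015,
                                      w_lo=1.0, w_hi=400.0)
    assert abs(achieved - 0.01) <= 0.0015
    # analytic inversion: dF = 0.002 + 0.5/(10+w) => w ~ 52.5
    assert 30 < w < 90


def test_calibrate_omega_endpoint_and_bracketing():
    def runner(w, rep):
        return 0.02 / np.sqrt(w)

    w, achieved, _ = calibrate_omega(runner, 0.02, 2, 0.001, w_lo=1.0, w_hi=100.0)
    assert w == 1.0 and achieved == pytest.approx(0.02)
    with pytest.raises(RuntimeError, match="not bracketed"):
        calibrate_omega(runner, 0.04, 2, 0.0005, w_lo=1.0, w_hi=100.0)
    with pytest.raises(ValueError):
        calibrate_omega(runner, 0.2, 2, 0.001)
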