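"""Optimum-contribution selection.

Contributions c of the selection candidates maximise

    U(c) = c' g_hat - w c' G c

subject to the scheme's mating structure: contributions sum to 1/2 within
each sex, every sire receives an integer number of the T matings
(c_male = m / 2T), and exactly T dams are selected with one mating each
(c_dam = 1 / 2T).  The penalty weight w >= 0 prices the mean relationship of
the selected group (larger w, stronger coancestry control).  Published
penalty grids are sometimes quoted with the opposite sign convention; use
``penalty_weight = abs(omega)``.

``solve_continuous`` solves the sex-constrained, non-negative continuous
relaxation by an active-set method on the KKT system.  ``solve_integer``
searches the discrete space of (integer sire mating vectors, dam subsets)
with a seeded evolutionary algorithm, elitist and warm-started from the
rounded continuous solution and a truncation-selection plan, so the returned
objective is never below either reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "OCSProblem",
    "ContributionSolution",
    "solve_continuous",
    "solve_integer",
    "mating_plan",
    "calibrate_omega",
]


@dataclass
class OCSProblem:
    gebv: np.ndarray
    G: np.ndarray  # candidate-restricted relationship matrix, same order
    sexes: np.ndarray  # "M"/"F" per candidate
    penalty_weight: float
    n_matings: int = 25
    offspring_per_mating: int = 20
    candidate_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gebv = np.asarray(self.gebv, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        self.sexes = np.asarray(self.sexes)
        n = self.gebv.size
        if self.G.shape != (n, n):
            raise ValueError("G must be square and match gebv length")
        if self.sexes.size != n:
            raise ValueError("one sex per candidate required")
        if self.n_matings < 1:
            raise ValueError("need at least one mating")
        if self.penalty_weight < 0:
            raise ValueError(
                "penalty_weight must be >= 0 (use abs() of a negatively "
                "quoted penalty)"
            )
        if self.candidate_ids is None:
            self.candidate_ids = np.arange(n, dtype=np.int64)

    @property
    def males(self) -> np.ndarray:
        return np.flatnonzero(self.sexes == "M")

    @property
    def females(self) -> np.ndarray:
        return np.flatnonzero(self.sexes == "F")


@dataclass
class ContributionSolution:
    """Feasible integer mating plan expressed as genetic contributions."""

    contributions: np.ndarray  # per candidate, >= 0, sums 1/2 per sex
    male_matings: np.ndarray  # integer matings per candidate (0 for females)
    dam_indices: np.ndarray  # the T selected dams (candidate indices)
    objective: float
    problem: OCSProblem
    trace: list = None  # (iteration, best objective) per EA generation

    def validate(self) -> None:
        p, c = self.problem, self.contributions
        t = p.n_matings
        males, females = p.males, p.females
        assert np.all(c >= -1e-12)
        assert abs(c[males].sum() - 0.5) < 1e-9
        assert abs(c[females].sum() - 0.5) < 1e-9
        assert self.male_matings.sum() == t
        assert np.all(self.male_matings[females] == 0)
        assert np.allclose(c[males], self.male_matings[males] / (2 * t))
        assert self.dam_indices.size == t
        assert np.unique(self.dam_indices).size == t
        assert np.allclose(c[self.dam_indices], 1.0 / (2 * t))


def _objective(problem: OCSProblem, c: np.ndarray, support: np.ndarray) -> float:
    cs = c[support]
    sub = problem.G[np.ix_(support, support)]
    return float(cs @ problem.gebv[support] - problem.penalty_weight * cs @ sub @ cs)


def objective_value(problem: OCSProblem, c: np.ndarray) -> float:
    """U(c) = c'g_hat - w c'Gc for an arbitrary contribution vector."""
    return _objective(problem, c, np.flatnonzero(c))


# ---------------------------------------------------------------------------
# continuous relaxation (active set)


def solve_continuous(problem: OCSProblem, tol: float = 1e-10, max_iter: int = 500) -> np.ndarray:
    """Maximise U(c) subject to per-sex sums of 1/2 and c >= 0.

    Active-set iteration on the KKT system of the equality-constrained
    subproblem; candidates driven negative are fixed at zero, and bound
    candidates whose KKT multiplier indicates improvement are freed again.
    With penalty_weight == 0 the objective is linear and the maximiser is a
    vertex: all contribution on the best candidate of each sex.
    """
    n = problem.gebv.size
    males, females = problem.males, problem.females
    if males.size == 0 or females.size == 0:
        raise ValueError("need candidates of both sexes")
    c = np.zeros(n)
    w = problem.penalty_weight
    if w <= tol:
        c[males[np.argmax(problem.gebv[males])]] = 0.5
        c[females[np.argmax(problem.gebv[females])]] = 0.5
        return c

    g = problem.gebv
    G = problem.G
    is_male = problem.sexes == "M"
    free = np.ones(n, dtype=bool)
    lam = np.zeros(2)
    for _ in range(max_iter):
        f = np.flatnonzero(free)
        s = np.vstack([is_male[f], ~is_male[f]]).astype(float)
        if s[0].sum() == 0 or s[1].sum() == 0:
            raise RuntimeError("active set lost all candidates of one sex")
        gff = 2.0 * w * G[np.ix_(f, f)]
        kkt = np.block([[gff, s.T], [s, np.zeros((2, 2))]])
        rhs = np.concatenate([g[f], [0.5, 0.5]])
        try:
            sol = np.linalg.solve(kkt, rhs)
        except np.linalg.LinAlgError:
            warnings.warn("singular KKT system; applying ridge to G")
            ridge = 1e-8 * max(np.mean(np.diag(G)), 1.0)
            gff = gff + 2.0 * w * ridge * np.eye(f.size)
            kkt = np.block([[gff, s.T], [s, np.zeros((2, 2))]])
            sol = np.linalg.solve(kkt, rhs)
        cf, lam = sol[:-2], sol[-2:]
        if cf.min() < -tol:
            drop = f[np.argmin(cf)]
            free[drop] = False
            continue
        c = np.zeros(n)
        c[f] = np.clip(cf, 0.0, None)
        # KKT multipliers of bound candidates: mu_i = g_i - 2w (Gc)_i - lam_sex
        bound = np.flatnonzero(~free)
        if bound.size:
            grad = g[bound] - 2.0 * w * (G[bound][:, f] @ cf)
            mu = grad - np.where(is_male[bound], lam[0], lam[1])
            if mu.max() > tol:
                free[bound[np.argmax(mu)]] = True
                continue
        return c
    raise RuntimeError("active-set iteration did not converge")


# ---------------------------------------------------------------------------
# integer search (evolutionary algorithm)


def _plan_contributions(problem: OCSProblem, m: np.ndarray, dams: np.ndarray) -> np.ndarray:
    t = problem.n_matings
    c = np.zeros(problem.gebv.size)
    males = problem.males
    c[males] = m / (2.0 * t)
    c[dams] = 1.0 / (2.0 * t)
    return c


def _plan_objective(problem: OCSProblem, m: np.ndarray, dams: np.ndarray) -> float:
    males = problem.males
    support = np.concatenate([males[m > 0], dams])
    c = _plan_contributions(problem, m, dams)
    return _objective(problem, c, support)


def _round_matings(cont_m: np.ndarray, t: int) -> np.ndarray:
    """Largest-remainder rounding of continuous male contributions to an
    integer mating vector summing to t."""
    raw = cont_m * 2.0 * t
    base = np.floor(raw).astype(np.int64)
    short = t - base.sum()
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    elif short < 0:
        order = np.argsort(raw - base, kind="stable")
        take = 0
        for i in order:
            if take == -short:
                break
            if base[i] > 0:
                base[i] -= 1
                take += 1
    return base


def _truncation_plan(problem: OCSProblem) -> tuple[np.ndarray, np.ndarray]:
    """Truncation-selection reference: matings spread as evenly as possible
    over the top-GEBV sires, dams the top T females."""
    t = problem.n_matings
    males, females = problem.males, problem.females
    n_sires = min(males.size, max(1, t // 5))
    order_m = males[np.argsort(-problem.gebv[males], kind="stable")]
    m = np.zeros(males.size, dtype=np.int64)
    top = {int(a): k for k, a in enumerate(order_m[:n_sires])}
    per, extra = divmod(t, n_sires)
    for a, k in top.items():
        m[np.flatnonzero(males == a)[0]] = per + (1 if k < extra else 0)
    order_f = females[np.argsort(-problem.gebv[females], kind="stable")]
    return m, np.sort(order_f[:t])


def _repair_matings(m: np.ndarray, t: int, rng: np.random.Generator) -> np.ndarray:
    m = np.maximum(m, 0)
    while m.sum() > t:
        pos = np.flatnonzero(m > 0)
        m[rng.choice(pos)] -= 1
    while m.sum() < t:
        m[rng.integers(m.size)] += 1
    return m


def solve_integer(
    problem: OCSProblem,
    rng: np.random.Generator | int | None = None,
    budget: int = 6000,
) -> ContributionSolution:
    """Evolutionary search over integer mating plans.

    The plan is (integer matings per sire summing to T, subset of T dams).
    The search is elitist and seeded with the rounded continuous optimum and
    a truncation plan, so its objective is never below either; it is exact
    on tiny instances (verified against enumeration in the test suite) and
    deterministic given the seed.
    """
    rng = np.random.default_rng(rng)
    t = problem.n_matings
    males, females = problem.males, problem.females
    if males.size < 1 or females.size < t:
        raise ValueError(
            f"infeasible: need >= 1 male and >= {t} females "
            f"(got {males.size} and {females.size})"
        )

    cont = solve_continuous(problem)
    seed_plans = [
        (_round_matings(cont[males], t), _seed_dams(problem, cont, rng)),
        _truncation_plan(problem),
    ]

    pop_size = 32
    n_gen = max(1, budget // pop_size)
    population: list[tuple[np.ndarray, np.ndarray]] = []
    for m, d in seed_plans:
        population.append((m.copy(), d.copy()))
    while len(population) < pop_size:
        m = _repair_matings(
            rng.multinomial(t, np.ones(males.size) / males.size), t, rng
        )
        d = np.sort(rng.choice(females, size=t, replace=False))
        population.append((m, d))

    def fitness(plan):
        return _plan_objective(problem, plan[0], plan[1])

    fits = np.array([fitness(p) for p in population])
    trace = [(0, float(fits.max()))]
    for it in range(n_gen):
        new_pop: list[tuple[np.ndarray, np.ndarray]] = []
        elite = np.argsort(-fits)[:2]
        for e in elite:
            new_pop.append(population[e])
        while len(new_pop) < pop_size:
            i, j = rng.integers(pop_size, size=2)
            pa = population[i] if fits[i] >= fits[j] else population[j]
            k, l = rng.integers(pop_size, size=2)
            pb = population[k] if fits[k] >= fits[l] else population[l]
            child = _crossover(pa, pb, problem, rng)
            child = _mutate_plan(child, problem, rng)
            new_pop.append(child)
        population = new_pop
        fits = np.array([fitness(p) for p in population])
        trace.append((it + 1, float(fits.max())))

    best = int(np.argmax(fits))
    m_best, d_best = population[best]
    c = _plan_contributions(problem, m_best, d_best)
    mm = np.zeros(problem.gebv.size, dtype=np.int64)
    mm[males] = m_best
    sol = ContributionSolution(c, mm, d_best, float(fits[best]), problem, trace=trace)
    sol.validate()
    return sol


def _seed_dams(problem: OCSProblem, cont: np.ndarray, rng) -> np.ndarray:
    females = problem.females
    t = problem.n_matings
    key = cont[females] + 1e-12 * problem.gebv[females]
    order = females[np.argsort(-key, kind="stable")]
    return np.sort(order[:t])


def _crossover(pa, pb, problem: OCSProblem, rng) -> tuple[np.ndarray, np.ndarray]:
    t = problem.n_matings
    mask = rng.random(pa[0].size) < 0.5
    m = np.where(mask, pa[0], pb[0]).astype(np.int64)
    m = _repair_matings(m, t, rng)
    pool = np.union1d(pa[1], pb[1])
    if pool.size >= t:
        d = np.sort(rng.choice(pool, size=t, replace=False))
    else:
        rest = np.setdiff1d(problem.females, pool)
        d = np.sort(
            np.concatenate([pool, rng.choice(rest, size=t - pool.size, replace=False)])
        )
    return m, d


def _mutate_plan(plan, problem: OCSProblem, rng) -> tuple[np.ndarray, np.ndarray]:
    m, d = plan[0].copy(), plan[1].copy()
    t = problem.n_matings
    if rng.random() < 0.8:
        pos = np.flatnonzero(m > 0)
        if pos.size:
            src = rng.choice(pos)
            dst = rng.integers(m.size)
            m[src] -= 1
            m[dst] += 1
    if rng.random() < 0.8:
        outside = np.setdiff1d(problem.females, d)
        if outside.size:
            d[rng.integers(t)] = rng.choice(outside)
            d = np.sort(d)
    return m, d


# ---------------------------------------------------------------------------
# mating plan and penalty calibration


def mating_plan(
    solution: ContributionSolution, rng: np.random.Generator | int | None = None
) -> list[tuple[int, int]]:
    """Random one-to-one pairing of sire mating slots with selected dams.

    Sire slots are the candidate indices repeated by mating count; dams are
    permuted uniformly.  Each pair produces ``offspring_per_mating``
    offspring in the scheme.
    """
    rng = np.random.default_rng(rng)
    p = solution.problem
    slots = np.repeat(np.arange(p.gebv.size), solution.male_matings)
    dams = rng.permutation(solution.dam_indices)
    return [(int(s), int(d)) for s, d in zip(slots, dams)]


def calibrate_omega(
    scheme_runner,
    target_dF: float,
    n_reps: int,
    tolerance: float,
    rng: np.random.Generator | int | None = None,
    w_lo: float = 1.0,
    w_hi: float = 200.0,
    max_iter: int = 12,
):
    """Find the penalty weight whose realised mean rate of true inbreeding
    matches ``target_dF``.

    ``scheme_runner(w, rep)`` must return the realised dF_true of one
    replicate at penalty weight ``w``.  Realised dF is non-increasing in w;
    the search is bisection on log(w), averaging ``n_reps`` replicates per
    evaluation.  Returns ``(w, achieved_mean, achieved_se)``.

    Raises RuntimeError with the achieved extremes if the target cannot be
    bracketed within [w_lo, w_hi].
    """
    if not 0.0 < target_dF <= 0.05:
        raise ValueError("target_dF must lie in (0, 0.05]")
    rng = np.random.default_rng(rng)

    def evaluate(w: float):
        vals = np.array([scheme_runner(w, rep) for rep in range(n_reps)])
        se = vals.std(ddof=1) / np.sqrt(n_reps) if n_reps > 1 else 0.0
        return float(vals.mean()), float(se)

    lo_val, lo_se = evaluate(w_lo)
    if abs(lo_val - target_dF) <= tolerance:
        return w_lo, lo_val, lo_se
    hi_val, hi_se = evaluate(w_hi)
    if abs(hi_val - target_dF) <= tolerance:
        return w_hi, hi_val, hi_se
    if not (hi_val <= target_dF <= lo_val):
        raise RuntimeError(
            f"target dF={target_dF} not bracketed: achieved "
            f"{lo_val:.4f} at w={w_lo} and {hi_val:.4f} at w={w_hi}"
        )
    a, b = np.log(w_lo), np.log(w_hi)
    best = (w_lo, lo_val, lo_se) if abs(lo_val - target_dF) < abs(hi_val - target_dF) else (w_hi, hi_val, hi_se)
    for _ in range(max_iter):
        mid = 0.5 * (a + b)
        w = float(np.exp(mid))
        val, se = evaluate(w)
        if abs(val - target_dF) < abs(best[1] - target_dF):
            best = (w, val, se)
        if abs(val - target_dF) <= tolerance:
            return w, val, se
        if val > target_dF:
            a = mid
        else:
            b = mid
    return best
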