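"""Inbreeding coefficients, rate estimators, aggregation."""

import numpy as np
import pandas as pd
import pytest

from gocsim import (
    aggregate,
    assign_ibd_alleles,
    gain_advantage_pct,
    pedigree_inbreeding,
    rate_of_gain,
    rate_of_inbreeding,
    sample_base,
    true_inbreeding,
)
from gocsim.metrics import ReplicateSummary, advantage_bounds_pct
from gocsim.population import FEMALE, MALE, make_offspring


# ---------------------------------------------------------------------------
# true (IBD tracer) inbreeding


def test_true_inbreeding_trivials():
    a = np.arange(10, dtype=np.int32)
    assert true_inbreeding((a, a + 10)) == 0.0
    assert true_inbreeding((a, a.copy())) == 1.0
    half = np.concatenate([a[:5], a[:5] + 50]).astype(np.int32)
    assert true_inbreeding((a, half)) == 0.5


def test_inbred_mating_mean_F_matches_classical_values(mini_founder):
    """Tracer-measured inbreeding recovers the classical pedigree
    expectations over repeated simulation of the same pedigree: 1/4 for a
    sire x daughter mating, 1/8 for paternal half sibs."""
    spec = mini_founder.spec
    rng = np.random.default_rng(0)
    f_pd, f_hs = [], []
    for _ in range(600):
        pop, base = sample_base(mini_founder, 1, 2, rng)
        assign_ibd_alleles(base, spec)
        sire, dam1, dam2 = base
        daughter = make_offspring(pop, sire, dam1, FEMALE, 1, spec, mini_founder.trait, rng)
        child = make_offspring(pop, sire, daughter, MALE, 2, spec, mini_founder.trait, rng)
        f_pd.append(true_inbreeding(child.ibd))
        son = make_offspring(pop, sire, dam2, MALE, 1, spec, mini_founder.trait, rng)
        hs_child = make_offspring(pop, son, daughter, MALE, 2, spec, mini_founder.trait, rng)
        f_hs.append(true_inbreeding(hs_child.ibd))
    for fs, expected in ((f_pd, 0.25), (f_hs, 0.125)):
        se = np.std(fs, ddof=1) / np.sqrt(len(fs))
        assert abs(np.mean(fs) - expected) < 3 * se


# ---------------------------------------------------------------------------
# pedigree inbreeding


def _path_counting_oracle(pedigree):
    """Independent naive kinship recursion: f(a,b) with memoisation."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def kinship(a, b):
        if a is None or b is None:
            return 0.0
        if a == b:
            s, d = pedigree[a]
            return 0.5 * (1.0 + kinship(s, d))
        # recurse on the younger animal (larger id = born later here)
        if a < b:
            a, b = b, a
        s, d = pedigree[a]
        return 0.5 * (kinship(s, b) + kinship(d, b))

    out = {}
    for a, (s, d) in pedigree.items():
        out[a] = kinship(s, d) if (s is not None and d is not None) else 0.0
    return out


def test_full_sib_mating_gives_quarter():
    ped = {1: (None, None), 2: (None, None), 3: (1, 2), 4: (1, 2), 5: (3, 4)}
    F = pedigree_inbreeding(ped)
    assert F[1] == F[2] == 0.0
    assert F[5] == pytest.approx(0.25)


def test_pedigree_matches_path_counting_oracle():
    rng = np.random.default_rng(1)
    ped = {i: (None, None) for i in range(10)}
    next_id = 10
    prev = list(range(10))
    for _gen in range(5):
        cur = []
        for _ in range(12):
            s, d = rng.choice(prev, size=2, replace=False)
            ped[next_id] = (int(s), int(d))
            cur.append(next_id)
            next_id += 1
        prev = cur
    mine = pedigree_inbreeding(ped)
    oracle = _path_counting_oracle(ped)
    for a in ped:
        assert mine[a] == pytest.approx(oracle[a], abs=1e-12)


def test_pedigree_cycle_rejected():
    with pytest.raises(ValueError, match="cycle"):
        pedigree_inbreeding({1: (2, None), 2: (1, None)})


# ---------------------------------------------------------------------------
# rates


def test_rate_of_gain_exact_on_linear_series():
    t = np.arange(6, 12)
    assert rate_of_gain(t, 0.6 * t + 2.0) == pytest.approx(0.6)
    assert rate_of_gain(t, np.full(6, 3.3)) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        rate_of_gain([1, 2], [0.0, 1.0])


def test_rate_of_inbreeding_inverts_geometric_series():
    t = np.arange(6, 12)
    f = 1 - (1 - 0.01) ** t
    assert rate_of_inbreeding(t, f) == pytest.approx(0.01, abs=1e-12)
    assert rate_of_inbreeding(t, np.full(6, 0.3)) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError, match="undefined"):
        rate_of_inbreeding(t, np.concatenate([f[:-1], [1.0]]))


def test_rate_of_inbreeding_recovers_rate_under_noise():
    rng = np.random.default_rng(2)
    t = np.arange(1, 12)
    rates = []
    for _ in range(400):
        f = 1 - (1 - 0.005) ** t * np.exp(rng.normal(0, 0.002, t.size))
        rates.append(rate_of_inbreeding(t, f))
    se = np.std(rates, ddof=1) / np.sqrt(len(rates))
    assert abs(np.mean(rates) - 0.005) < 3 * se


def test_rate_of_gain_unbiased_under_noise():
    rng = np.random.default_rng(3)
    t = np.arange(6, 12)
    slopes = [
        rate_of_gain(t, 0.4 * t + rng.normal(0, 0.3, t.size)) for _ in range(2000)
    ]
    se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
    assert abs(np.mean(slopes) - 0.4) < 3 * se


# ---------------------------------------------------------------------------
# aggregation and table comparisons


def _summary(**kw):
    base = dict(dG=0.5, dF_true=0.01, dF_ped=0.01, accuracy_male=0.7,
                accuracy_female=0.7)
    base.update(kw)
    return ReplicateSummary(**base)


def test_aggregate_mean_and_se():
    table = aggregate([_summary(dG=0.6), _summary(dG=0.8)])
    assert table.loc["dG", "mean"] == pytest.approx(0.7)
    assert table.loc["dG", "se"] == pytest.approx(0.1)
    same = aggregate([_summary(), _summary(), _summary()])
    assert np.allclose(same["se"], 0.0)
    with pytest.raises(ValueError):
        aggregate([_summary()])


def test_advantage_statistics_on_synthetic_table():
    table = pd.DataFrame(
        {"dG": [1.2, 1.0, 0.8]},
        index=pd.Index(["Q_M", "M_A", "M_M"], name="scenario"),
    )
    assert gain_advantage_pct(table, "Q_M", "M_M", "dG") == pytest.approx(50.0)
    lo, hi = advantage_bounds_pct(table, focal=("Q_M",), column="dG")
    assert lo == pytest.approx(20.0)
    assert hi == pytest.approx(50.0)
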