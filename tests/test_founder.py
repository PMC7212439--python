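"""Founder simulation: meiosis, mutation, effects, selection, equilibrium."""

import numpy as np
import pytest

from gocsim import GenomeSpec, run_founder, sample_qtl_effects, standardize_effects, subsample_qtl
from gocsim.founder import (
    TraitModel,
    _FounderState,
    compute_tbv,
    draw_crossovers,
    founder_selection_step,
    meiosis,
    mutate_gamete,
    recombine,
)

EMPTY = np.empty(0, dtype=np.int64)


# ---------------------------------------------------------------------------
# meiosis


def test_meiosis_identical_parents_returns_parent():
    spec = GenomeSpec.reduced()
    rng = np.random.default_rng(0)
    hap = np.sort(rng.choice(spec.n_loci, size=200, replace=False)).astype(np.int64)
    for _ in range(5):
        gamete = meiosis((hap, hap.copy()), spec, rng)
        assert np.array_equal(gamete, hap)


def test_meiosis_mean_crossovers_matches_map_length():
    spec = GenomeSpec.full_scale()
    rng = np.random.default_rng(1)
    n = 4000
    counts = np.array([draw_crossovers(spec, rng)[0].size for _ in range(n)])
    se = np.sqrt(spec.length_morgans / n)
    assert abs(counts.mean() - 30.06) < 3 * se


def test_recombination_fraction_matches_haldane():
    """Fraction of recombinant gametes between two loci follows the Haldane
    map function r = (1 - exp(-2d)) / 2 under the no-interference model."""
    spec = GenomeSpec(n_chromosomes=1, chrom_length_cM=100.0, loci_per_cM=1.0,
                      ibd_loci_per_cM=1.0)
    first, last = 0, spec.n_loci - 1
    d_morgans = (spec.locus_pos_cM([last])[0] - spec.locus_pos_cM([first])[0]) / 100.0
    expected = 0.5 * (1.0 - np.exp(-2.0 * d_morgans))
    h0 = np.array([first], dtype=np.int64)
    h1 = np.array([last], dtype=np.int64)
    rng = np.random.default_rng(2)
    n = 20000
    rec = 0
    for _ in range(n):
        g = meiosis((h0, h1), spec, rng)
        if g.size != 1:  # both or neither end allele: a recombinant gamete
            rec += 1
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(rec / n - expected) < 3 * se


def test_gamete_sorted_and_subset_of_parents():
    spec = GenomeSpec.reduced()
    rng = np.random.default_rng(3)
    h0 = np.sort(rng.choice(spec.n_loci, size=300, replace=False)).astype(np.int64)
    h1 = np.sort(rng.choice(spec.n_loci, size=250, replace=False)).astype(np.int64)
    union = set(h0) | set(h1)
    for _ in range(10):
        g = recombine(spec, (h0, h1), rng)
        assert np.all(np.diff(g) > 0)
        assert set(g.tolist()) <= union


# ---------------------------------------------------------------------------
# mutation


def test_mutation_rate_zero_is_identity():
    spec = GenomeSpec(n_chromosomes=1, chrom_length_cM=10, loci_per_cM=10,
                      mutation_rate=0.0)
    g = np.array([3, 7], dtype=np.int64)
    out = mutate_gamete(g, spec, set(), np.random.default_rng(0))
    assert np.array_equal(out, g)


def test_mutation_mean_count_matches_binomial():
    spec = GenomeSpec.reduced()  # 20,000 loci at rate 4e-5: mean 0.8/gamete
    rng = np.random.default_rng(4)
    n = 4000
    total = sum(
        mutate_gamete(EMPTY, spec, set(), rng).size for _ in range(n)
    )
    mean = spec.n_loci * spec.mutation_rate
    se = np.sqrt(mean / n)
    assert abs(total / n - mean) < 3 * se


def test_mutation_avoids_occupied_loci():
    spec = GenomeSpec(n_chromosomes=1, chrom_length_cM=1.0, loci_per_cM=10.0,
                      mutation_rate=0.3)
    occupied = set(range(5))
    rng = np.random.default_rng(5)
    for _ in range(50):
        out = mutate_gamete(EMPTY, spec, occupied, rng)
        assert not (set(out.tolist()) & occupied)


# ---------------------------------------------------------------------------
# QTL effects


def test_qtl_effect_sign_and_magnitude():
    rng = np.random.default_rng(6)
    t = sample_qtl_effects(np.arange(100_000), rng)
    frac_pos = np.mean(t.effects > 0)
    assert abs(frac_pos - 0.1) < 3 * np.sqrt(0.09 / 100_000)
    assert np.all(t.effects != 0.0)
    assert abs(np.mean(np.abs(t.effects)) - 1.0) < 3 / np.sqrt(100_000)


def test_standardize_two_animal_toy():
    """One QTL, genotypes 0 and 2 copies, raw effect 3: the scalar is 1/3,
    TBVs become {0, 2}, population variance 1."""
    q = np.array([4], dtype=np.int64)
    trait = TraitModel(q, np.array([3.0]))
    animals = [(EMPTY, EMPTY), (q, q.copy())]
    std = standardize_effects(trait, animals)
    assert std.effects[0] == pytest.approx(1.0)
    tbvs = [compute_tbv(a, std) for a in animals]
    assert tbvs == pytest.approx([0.0, 2.0])
    assert np.var(tbvs) == pytest.approx(1.0, abs=1e-10)


def test_standardize_scale_invariance_and_zero_variance():
    q = np.array([1, 5], dtype=np.int64)
    animals = [(np.array([1]), EMPTY), (np.array([5]), np.array([5]))]
    a = standardize_effects(TraitModel(q, np.array([0.5, -2.0])), animals)
    b = standardize_effects(TraitModel(q, np.array([1.0, -4.0])), animals)
    assert np.allclose(a.effects, b.effects)
    with pytest.raises(ValueError, match="variance is zero"):
        standardize_effects(TraitModel(q, np.array([1.0, 1.0])), [(EMPTY, EMPTY)])


def test_subsample_qtl(reduced_founder):
    pairs = reduced_founder.founder_hap_pairs()
    trait = reduced_founder.trait
    sub = subsample_qtl(trait, 20, pairs, np.random.default_rng(0))
    assert sub.qtl_ids.size == 20
    assert np.all(np.isin(sub.qtl_ids, trait.qtl_ids))
    tbvs = [compute_tbv(p, sub) for p in pairs]
    assert np.var(tbvs) == pytest.approx(1.0, abs=1e-10)
    full = subsample_qtl(trait, trait.qtl_ids.size, pairs, np.random.default_rng(0))
    assert np.array_equal(full.qtl_ids, trait.qtl_ids)
    with pytest.raises(ValueError):
        subsample_qtl(trait, trait.qtl_ids.size + 1, pairs, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# selection step


def test_cull_count_ceiling():
    rng = np.random.default_rng(7)
    tbvs = rng.normal(size=50)
    culled = founder_selection_step(tbvs, 0.05, rng)
    assert culled.size == 3  # ceil(2.5)
    assert set(culled.tolist()) == set(np.argsort(tbvs)[:3].tolist())
    assert founder_selection_step(tbvs, 0.0, rng).size == 0


def test_cull_ties_broken_randomly():
    tbvs = np.zeros(20)
    picks = {
        tuple(founder_selection_step(tbvs, 0.1, np.random.default_rng(s)).tolist())
        for s in range(20)
    }
    assert len(picks) > 1


# ---------------------------------------------------------------------------
# whole founder run


def test_no_mutation_gives_empty_table():
    spec = GenomeSpec(n_chromosomes=1, chrom_length_cM=10, loci_per_cM=10,
                      mutation_rate=0.0)
    out = run_founder(spec, 3, pop_size=10, rng=np.random.default_rng(0))
    assert len(out.loci_table) == 0


def test_founder_output_consistency(mini_founder):
    t = mini_founder.loci_table
    assert len(t) > 0
    assert np.all((t["freq"] > 0) & (t["freq"] < 1))
    assert set(t["klass"]) <= {"M", "Q"}
    assert np.all(np.diff(t["locus"]) > 0)
    # trait variance standardised over the founder animals
    tbvs = [compute_tbv(p, mini_founder.trait) for p in mini_founder.founder_hap_pairs()]
    assert np.var(tbvs) == pytest.approx(1.0, abs=1e-8)
    # pools: haplotypes only carry segregating loci
    seg = set(t["locus"].tolist())
    for c in range(mini_founder.spec.n_chromosomes):
        for h in mini_founder.pools[c][:10]:
            assert set(h.tolist()) <= seg


def test_haplotype_frequencies_match_table(mini_founder):
    """The table's frequencies are the realised counts over the 2N pool
    haplotypes."""
    t = mini_founder.loci_table
    n_hap = mini_founder.n_haplotypes
    haps = [mini_founder.founder_haplotype(j) for j in range(n_hap)]
    counts = {}
    for h in haps:
        for l in h.tolist():
            counts[l] = counts.get(l, 0) + 1
    for row in t.itertuples():
        assert counts[row.locus] / n_hap == pytest.approx(row.freq)


def test_neutral_single_locus_frequency_conserved():
    """With no culling and no mutation, the expected derived-allele
    frequency is constant across a Wright-Fisher generation."""
    spec = GenomeSpec(n_chromosomes=1, chrom_length_cM=10, loci_per_cM=10,
                      mutation_rate=0.0)
    rng = np.random.default_rng(8)
    p0 = 0.3
    freqs = []
    for _ in range(300):
        state = _FounderState(spec, 20, rng)
        carriers = rng.choice(40, size=int(p0 * 40), replace=False)
        locus = np.array([3], dtype=np.int64)
        k = 0
        for group in (state.male_haps, state.female_haps):
            for i in range(len(group)):
                pair = []
                for _h in range(2):
                    pair.append(locus.copy() if k in carriers else EMPTY.copy())
                    k += 1
                group[i] = tuple(pair)
        offspring = [state.make_offspring(rng) for _ in range(20)]
        count = sum(h.size for pair in offspring for h in pair)
        freqs.append(count / 40)
    se = np.std(freqs, ddof=1) / np.sqrt(len(freqs))
    assert abs(np.mean(freqs) - p0) < 3 * se


def test_neutral_heterozygosity_matches_wright_fisher_oracle():
    """Mean heterozygosity per segregating locus agrees with an independent
    single-locus Wright-Fisher Monte-Carlo at the same mutation rate and Ne
    (linkage does not alter single-locus frequency dynamics under
    neutrality)."""
    spec = GenomeSpec(n_chromosomes=1, chrom_length_cM=50.0, loci_per_cM=100.0,
                      mutation_rate=4e-5, ibd_loci_per_cM=1.0)
    n_gen, pop = 150, 50
    out = run_founder(spec, n_gen, pop_size=pop, cull_fraction=0.0,
                      rng=np.random.default_rng(9))
    p = out.loci_table["freq"].to_numpy()
    sim_het = np.mean(2 * p * (1 - p))

    def oracle(seed):
        rng = np.random.default_rng(seed)
        n2 = 2 * pop
        x = np.zeros(spec.n_loci, dtype=np.int64)
        for _ in range(n_gen):
            seg = (x > 0) & (x < n2)
            x[seg] = rng.binomial(n2, x[seg] / n2)
            x[x == n2] = 0  # fixed derived: drop, locus free again
            mono = x == 0
            x[mono] = rng.binomial(n2, spec.mutation_rate, size=mono.sum())
        q = x[(x > 0) & (x < n2)] / n2
        return np.mean(2 * q * (1 - q))

    vals = np.array([oracle(100 + i) for i in range(6)])
    spread = vals.std(ddof=1)
    assert abs(sim_het - vals.mean()) < 4 * spread
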