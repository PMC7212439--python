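"""Forward-in-time founder population under mutation, drift, recombination
and mild directional selection.

A founder population of constant size (equal sexes) is propagated for a
configurable number of discrete Wright-Fisher generations.  Haplotypes are
stored sparsely as sorted arrays of candidate-locus identifiers at which the
derived (mutant) allele is carried; at full scale a dense representation over
3e7 loci would be prohibitive.  Meiosis draws a Poisson number of crossovers
(mean = genome length in Morgans) placed uniformly on the genome, with an
independent fair coin per chromosome for the starting parental strand — a
no-interference (Haldane) recombination model.  Mutation converts currently
monomorphic loci to carry the derived allele on one gamete.

Each candidate locus is permanently either a marker or a QTL-class locus; the
class is drawn (QTL with probability ``qtl_fraction``) the first time the
locus mutates and memoised, which is distributionally identical to assigning
classes to the whole grid up front.  The derived allele at a QTL carries an
additive effect: magnitude exponential, sign positive with probability 0.1.
Mild directional selection is applied by culling the lowest ~5% of each
generation by true breeding value and replacing them in a single resampling
pass.

At the end of the run the surviving generation's haplotypes are split into
per-chromosome pools (2 * pop_size chromosome copies per pool), monomorphic
loci are dropped, and QTL effects are standardised so the founder generation
has additive-genetic variance exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeSpec

__all__ = [
    "FounderOutput",
    "TraitModel",
    "draw_crossovers",
    "recombine",
    "meiosis",
    "mutate_gamete",
    "sample_qtl_effects",
    "standardize_effects",
    "subsample_qtl",
    "founder_selection_step",
    "run_founder",
    "compute_tbv",
]

_EMPTY = np.empty(0, dtype=np.int64)


# ---------------------------------------------------------------------------
# trait model


@dataclass
class TraitModel:
    """QTL identities and standardised additive effects of the derived allele.

    ``qtl_ids`` is sorted; ``effects`` is aligned with it.  The ancestral
    allele has effect 0 at every locus, so an individual's true breeding
    value is the dosage-weighted sum of effects over its trait QTL.
    """

    qtl_ids: np.ndarray
    effects: np.ndarray
    scale_applied: float = 1.0

    def __post_init__(self) -> None:
        self.qtl_ids = np.asarray(self.qtl_ids, dtype=np.int64)
        self.effects = np.asarray(self.effects, dtype=float)
        if self.qtl_ids.shape != self.effects.shape:
            raise ValueError("qtl_ids and effects must align")
        if self.qtl_ids.size > 1 and np.any(np.diff(self.qtl_ids) <= 0):
            raise ValueError("qtl_ids must be strictly increasing")

    def haplotype_value(self, hap: np.ndarray) -> float:
        """Sum of effects of trait QTL carried on one haplotype."""
        if hap.size == 0 or self.qtl_ids.size == 0:
            return 0.0
        idx = np.searchsorted(self.qtl_ids, hap)
        ok = idx < self.qtl_ids.size
        ok[ok] = self.qtl_ids[idx[ok]] == hap[ok]
        return float(self.effects[idx[ok]].sum())


def compute_tbv(hap_pair, trait: TraitModel) -> float:
    """True breeding value: sum over trait QTL of mutant-allele dosage times
    the additive effect."""
    h0, h1 = hap_pair
    return trait.haplotype_value(h0) + trait.haplotype_value(h1)


# ---------------------------------------------------------------------------
# meiosis


def draw_crossovers(spec: GenomeSpec, rng: np.random.Generator):
    """Sample one meiosis' crossover pattern.

    Returns ``(breakpoints, starts)``: a sorted array of crossover positions
    (count ~ Poisson(genome length in Morgans), uniform on the concatenated
    genome — the no-interference model) and the starting parental strand per
    chromosome (fair coin each).
    """
    n_x = rng.poisson(spec.length_morgans)
    bp = np.sort(rng.uniform(0.0, spec.total_cM, size=n_x))
    starts = rng.integers(0, 2, size=spec.n_chromosomes)
    return bp, starts


def recombine(
    spec: GenomeSpec,
    haps: tuple[np.ndarray, np.ndarray],
    rng: np.random.Generator,
    ibd: tuple[np.ndarray, np.ndarray] | None = None,
):
    """Form one gamete from a pair of parental haplotypes.

    Crossover count ~ Poisson(genome length in Morgans), positions uniform on
    the concatenated genome; within each chromosome the gamete alternates
    parental strands at crossover points, starting from a randomly chosen
    strand per chromosome.  If ``ibd`` label arrays are given, the tracer
    labels are transmitted through the identical crossover pattern and the
    function returns ``(gamete_ids, gamete_ibd)``; otherwise just the sparse
    gamete.
    """
    bp, starts = draw_crossovers(spec, rng)

    pieces: list[np.ndarray] = []
    ibd_pieces: list[np.ndarray] = []
    L = spec.chrom_length_cM
    for c in range(spec.n_chromosomes):
        lo, hi = c * L, (c + 1) * L
        within = bp[(bp > lo) & (bp < hi)]
        edges = np.concatenate(([lo], within, [hi]))
        strand = int(starts[c])
        for a, b in zip(edges[:-1], edges[1:]):
            src = haps[strand]
            i0 = np.searchsorted(src, spec.n_loci_below(a))
            i1 = np.searchsorted(src, spec.n_loci_below(b))
            if i1 > i0:
                pieces.append(src[i0:i1])
            if ibd is not None:
                j0, j1 = spec.n_ibd_below(a), spec.n_ibd_below(b)
                if j1 > j0:
                    ibd_pieces.append(ibd[strand][j0:j1])
            strand ^= 1

    gamete = np.concatenate(pieces) if pieces else _EMPTY.copy()
    if ibd is None:
        return gamete
    gamete_ibd = (
        np.concatenate(ibd_pieces)
        if ibd_pieces
        else np.empty(0, dtype=ibd[0].dtype)
    )
    return gamete, gamete_ibd


def meiosis(parent_haps, spec: GenomeSpec, rng: np.random.Generator) -> np.ndarray:
    """One gamete (sparse derived-allele id array) from a parental haplotype
    pair, without tracer loci."""
    return recombine(spec, parent_haps, rng)


# ---------------------------------------------------------------------------
# mutation


def mutate_gamete(
    gamete: np.ndarray,
    spec: GenomeSpec,
    occupied,
    rng: np.random.Generator,
) -> np.ndarray:
    """Add new mutations to a gamete.

    ``occupied`` is the set of loci unavailable to mutation: currently
    segregating loci plus loci already fixed for the derived allele.  The
    number of new mutations is Binomial(#monomorphic loci, rate); each hits a
    uniformly chosen available locus (per-locus infinite-sites approximation:
    no recurrent or back mutation).
    """
    if spec.mutation_rate == 0.0:
        return gamete
    n_mono = spec.n_loci - len(occupied)
    if n_mono <= 0:
        return gamete
    n_new = rng.binomial(n_mono, spec.mutation_rate)
    if n_new == 0:
        return gamete
    chosen: set[int] = set()
    present = set(gamete.tolist())
    while len(chosen) < n_new:
        cand = int(rng.integers(0, spec.n_loci))
        if cand in occupied or cand in chosen or cand in present:
            continue
        chosen.add(cand)
    out = np.concatenate([gamete, np.fromiter(chosen, dtype=np.int64, count=len(chosen))])
    out.sort()
    return out


# ---------------------------------------------------------------------------
# QTL effects


def sample_qtl_effects(qtl_ids, rng: np.random.Generator, scale: float = 1.0) -> TraitModel:
    """Raw (unstandardised) additive effects for a list of QTL loci.

    Magnitudes are Exponential(scale); the sign is positive with probability
    0.1, negative otherwise.  The ancestral allele always has effect 0.
    """
    qtl_ids = np.asarray(sorted(qtl_ids), dtype=np.int64)
    if qtl_ids.size == 0:
        raise ValueError("QTL locus list is empty")
    mag = rng.exponential(scale, size=qtl_ids.size)
    sign = np.where(rng.random(qtl_ids.size) < 0.1, 1.0, -1.0)
    return TraitModel(qtl_ids, mag * sign)


def _reference_tbvs(trait: TraitModel, reference_haps) -> np.ndarray:
    return np.array([compute_tbv(pair, trait) for pair in reference_haps])


def standardize_effects(trait: TraitModel, reference_haps) -> TraitModel:
    """Scale all effects by one scalar so the population variance (divide by
    n) of TBV over the reference animals is exactly 1.

    Raises if the reference TBVs have zero variance (no segregating QTL with
    effect among the reference animals).
    """
    tbvs = _reference_tbvs(trait, reference_haps)
    var = float(np.var(tbvs))  # population convention, ddof=0
    if var <= 0.0:
        raise ValueError(
            "additive variance is zero before standardisation: "
            "no QTL segregates with effect among the reference animals"
        )
    s = 1.0 / np.sqrt(var)
    return TraitModel(trait.qtl_ids, trait.effects * s, trait.scale_applied * s)


def subsample_qtl(
    trait: TraitModel,
    n_target: int,
    reference_haps,
    rng: np.random.Generator,
) -> TraitModel:
    """Uniform random subset of ``n_target`` trait QTL, re-standardised to
    additive variance 1 over the reference animals.  Removed QTL cease to
    exist for the trait (and are excluded from every relationship matrix)."""
    if n_target > trait.qtl_ids.size:
        raise ValueError(
            f"requested {n_target} QTL but only {trait.qtl_ids.size} segregate"
        )
    keep = np.sort(rng.choice(trait.qtl_ids.size, size=n_target, replace=False))
    sub = TraitModel(trait.qtl_ids[keep], trait.effects[keep], trait.scale_applied)
    return standardize_effects(sub, reference_haps)


# ---------------------------------------------------------------------------
# founder output container


@dataclass
class FounderOutput:
    """Chromosome pools and locus bookkeeping of the final founder generation.

    ``pools[c]`` is the list of 2*pop_size chromosome-c haplotype copies
    (sparse, restricted to segregating loci); copy ``j`` across all
    chromosomes belongs to the same founder haplotype, so founder animal
    ``i`` carries copies ``2i`` and ``2i + 1``.
    """

    spec: GenomeSpec
    pools: list  # per chromosome: list of sorted int64 arrays
    loci_table: pd.DataFrame  # locus, chrom, pos_cM, klass, freq
    trait: TraitModel
    locus_class: dict = field(default_factory=dict, repr=False)

    @property
    def n_haplotypes(self) -> int:
        return len(self.pools[0])

    def founder_haplotype(self, j: int) -> np.ndarray:
        """Genome-wide sparse haplotype of pool copy ``j``."""
        parts = [self.pools[c][j] for c in range(self.spec.n_chromosomes)]
        return np.concatenate(parts) if parts else _EMPTY.copy()

    def founder_hap_pairs(self):
        """Haplotype pairs of the pop_size founder animals (for trait
        standardisation)."""
        n = self.n_haplotypes // 2
        return [
            (self.founder_haplotype(2 * i), self.founder_haplotype(2 * i + 1))
            for i in range(n)
        ]

    def marker_ids(self) -> np.ndarray:
        t = self.loci_table
        return t.loc[t["klass"] == "M", "locus"].to_numpy(dtype=np.int64)

    def qtl_ids(self) -> np.ndarray:
        t = self.loci_table
        return t.loc[t["klass"] == "Q", "locus"].to_numpy(dtype=np.int64)


# ---------------------------------------------------------------------------
# founder generation step


def _tbv_array(haps, trait: TraitModel) -> np.ndarray:
    return np.array([compute_tbv(pair, trait) for pair in haps])


def founder_selection_step(
    tbvs: np.ndarray,
    cull_fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Indices of animals to cull: the lowest ceil(cull_fraction * N) by TBV.

    Ties are broken randomly (a random permutation is applied before the
    stable sort), which only matters in the effect-free early generations.
    """
    n = tbvs.size
    n_cull = int(np.ceil(cull_fraction * n))
    if n_cull == 0:
        return np.empty(0, dtype=np.int64)
    perm = rng.permutation(n)
    order = perm[np.argsort(tbvs[perm], kind="stable")]
    return np.sort(order[:n_cull])


class _FounderState:
    """Mutable per-generation bookkeeping for the founder run."""

    def __init__(self, spec: GenomeSpec, pop_size: int, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        half = pop_size // 2
        self.male_haps = [(_EMPTY.copy(), _EMPTY.copy()) for _ in range(half)]
        self.female_haps = [(_EMPTY.copy(), _EMPTY.copy()) for _ in range(half)]
        self.occupied: set[int] = set()       # segregating or fixed-derived
        self.fixed: set[int] = set()          # fixed for the derived allele
        self.locus_class: dict[int, str] = {} # memoised marker/QTL class
        self.raw_eff: dict[int, float] = {}   # raw effect per QTL-class locus
        self.seg_freq: dict[int, float] = {}

    # -- trait handling on raw effects -----------------------------------

    def raw_trait(self) -> TraitModel:
        if not self.raw_eff:
            return TraitModel(_EMPTY.copy(), np.empty(0))
        ids = np.array(sorted(self.raw_eff), dtype=np.int64)
        eff = np.array([self.raw_eff[i] for i in ids])
        return TraitModel(ids, eff)

    def classify_new(self, loci) -> None:
        for l in loci:
            li = int(l)
            if li in self.locus_class:
                continue
            if self.rng.random() < self.spec.qtl_fraction:
                self.locus_class[li] = "Q"
                mag = self.rng.exponential(1.0)
                sign = 1.0 if self.rng.random() < 0.1 else -1.0
                self.raw_eff[li] = mag * sign
            else:
                self.locus_class[li] = "M"

    def make_offspring(self, rng: np.random.Generator):
        sire = self.male_haps[rng.integers(len(self.male_haps))]
        dam = self.female_haps[rng.integers(len(self.female_haps))]
        g1 = mutate_gamete(recombine(self.spec, sire, rng), self.spec, self.occupied, rng)
        g2 = mutate_gamete(recombine(self.spec, dam, rng), self.spec, self.occupied, rng)
        self.classify_new(np.concatenate([g1, g2]))
        return (g1, g2)

    def refresh_frequencies(self) -> None:
        """Recount derived-allele frequencies; drop fixed loci from every
        haplotype and free lost loci for future mutation."""
        n_hap = 2 * (len(self.male_haps) + len(self.female_haps))
        flat = [h for pair in self.male_haps + self.female_haps for h in pair if h.size]
        if flat:
            ids, counts = np.unique(np.concatenate(flat), return_counts=True)
        else:
            ids, counts = _EMPTY.copy(), np.empty(0, dtype=np.int64)
        fixed_now = ids[counts == n_hap]
        seg_ids = ids[counts < n_hap]
        seg_counts = counts[counts < n_hap]
        if fixed_now.size:
            for group in (self.male_haps, self.female_haps):
                for i, pair in enumerate(group):
                    group[i] = (
                        pair[0][~np.isin(pair[0], fixed_now)],
                        pair[1][~np.isin(pair[1], fixed_now)],
                    )
            self.fixed |= set(fixed_now.tolist())
        self.occupied = set(seg_ids.tolist()) | self.fixed
        self.seg_freq = {int(i): c / n_hap for i, c in zip(seg_ids, seg_counts)}


def run_founder(
    spec: GenomeSpec,
    n_generations: int,
    pop_size: int = 50,
    cull_fraction: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> FounderOutput:
    """Simulate the historical founder population and return its chromosome
    pools, segregating-locus table, and standardised trait model.

    ``pop_size`` animals (half per sex) are propagated for ``n_generations``
    discrete generations; parents of each offspring are drawn with
    replacement from the previous generation's survivors, and each
    generation the lowest ``cull_fraction`` of animals by TBV are replaced in
    one resampling pass.
    """
    if pop_size % 2:
        raise ValueError("pop_size must be even (equal males and females)")
    if n_generations < 1:
        raise ValueError("need at least one generation")
    rng = np.random.default_rng(rng)

    state = _FounderState(spec, pop_size, rng)
    half = pop_size // 2

    for _ in range(n_generations):
        offspring = [state.make_offspring(rng) for _ in range(pop_size)]
        trait = state.raw_trait()
        tbvs = _tbv_array(offspring, trait)
        cull = founder_selection_step(tbvs, cull_fraction, rng)
        for idx in cull:
            offspring[idx] = state.make_offspring(rng)
        sex_order = rng.permutation(pop_size)
        state.male_haps = [offspring[i] for i in sex_order[:half]]
        state.female_haps = [offspring[i] for i in sex_order[half:]]
        state.refresh_frequencies()

    if not state.seg_freq:
        if spec.mutation_rate == 0.0:
            # degenerate but well-defined: no mutation can never polymorphise
            empty_table = pd.DataFrame(
                {"locus": _EMPTY.copy(), "chrom": _EMPTY.copy(),
                 "pos_cM": np.empty(0), "klass": np.empty(0, dtype=object),
                 "freq": np.empty(0)}
            )
            pools = [
                [h.copy() for pair in state.male_haps + state.female_haps for h in pair]
                for _ in range(spec.n_chromosomes)
            ]
            return FounderOutput(
                spec, pools, empty_table, TraitModel(_EMPTY.copy(), np.empty(0))
            )
        raise RuntimeError(
            "no segregating loci at the end of the founder simulation; "
            "increase the mutation rate or the number of generations"
        )

    seg_ids = np.array(sorted(state.seg_freq), dtype=np.int64)
    freqs = np.array([state.seg_freq[int(i)] for i in seg_ids])
    klass = np.array([state.locus_class[int(i)] for i in seg_ids])
    table = pd.DataFrame(
        {
            "locus": seg_ids,
            "chrom": spec.locus_chrom(seg_ids),
            "pos_cM": spec.locus_pos_cM(seg_ids),
            "klass": klass,
            "freq": freqs,
        }
    )

    all_haps = state.male_haps + state.female_haps
    pools: list[list[np.ndarray]] = []
    bounds = [c * spec.loci_per_chrom for c in range(spec.n_chromosomes + 1)]
    for c in range(spec.n_chromosomes):
        pool_c = []
        for pair in all_haps:
            for h in pair:
                i0, i1 = np.searchsorted(h, [bounds[c], bounds[c + 1]])
                pool_c.append(h[i0:i1].copy())
        pools.append(pool_c)

    qtl_seg = seg_ids[klass == "Q"]
    if qtl_seg.size == 0:
        raise RuntimeError("no QTL segregates at the end of the founder simulation")
    raw = TraitModel(qtl_seg, np.array([state.raw_eff[int(i)] for i in qtl_seg]))
    trait = standardize_effects(raw, all_haps)

    return FounderOutput(spec, pools, table, trait, dict(state.locus_class))
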