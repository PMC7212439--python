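"""Individuals, pedigree bookkeeping, and base-population sampling.

The base population that initiates a breeding scheme is drawn from the
founder chromosome pools: for each animal and each chromosome, two
chromosome copies are sampled without replacement from that chromosome's
pool, and the pool is restored before the next animal is drawn, so base
animals may share founder chromosomes.  Base animals are treated as
unrelated and non-inbred: every one of the 2n base haplotypes gets its own
unique integer label at every IBD tracer locus, so identity of labels in any
later generation certifies identity-by-descent with respect to the base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .founder import FounderOutput, TraitModel, compute_tbv, recombine
from .genome import GenomeSpec

__all__ = ["Individual", "Population", "sample_base", "assign_ibd_alleles"]

MALE = "M"
FEMALE = "F"


@dataclass
class Individual:
    id: int
    sex: str  # "M" or "F"
    sire: int | None
    dam: int | None
    generation: int
    hap: tuple[np.ndarray, np.ndarray]
    ibd: tuple[np.ndarray, np.ndarray] | None = None
    tbv: float = 0.0
    phenotype: float | None = None

    @property
    def is_base(self) -> bool:
        return self.sire is None and self.dam is None

    def dosage(self, loci: np.ndarray) -> np.ndarray:
        """Mutant-allele dosage (0/1/2) at the given sorted locus ids."""
        out = np.zeros(loci.size, dtype=np.int8)
        for h in self.hap:
            if h.size == 0:
                continue
            idx = np.searchsorted(loci, h)
            ok = idx < loci.size
            ok[ok] = loci[idx[ok]] == h[ok]
            out[idx[ok]] += 1
        return out


class Population:
    """Ordered collection of individuals with pedigree links."""

    def __init__(self) -> None:
        self._by_id: dict[int, Individual] = {}
        self._next_id = 0

    def new_id(self) -> int:
        i = self._next_id
        self._next_id += 1
        return i

    def add(self, ind: Individual) -> Individual:
        if ind.id in self._by_id:
            raise ValueError(f"duplicate animal id {ind.id}")
        self._by_id[ind.id] = ind
        return ind

    def __getitem__(self, animal_id: int) -> Individual:
        return self._by_id[animal_id]

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self):
        return iter(self._by_id.values())

    def generation(self, t: int) -> list[Individual]:
        return [a for a in self if a.generation == t]

    def pedigree(self) -> dict[int, tuple[int | None, int | None]]:
        """child -> (sire, dam) over all individuals (None for base parents)."""
        return {a.id: (a.sire, a.dam) for a in self}

    def dosage_matrix(self, animals, loci: np.ndarray) -> np.ndarray:
        """Animals x loci dosage matrix (int8) at sorted locus ids."""
        return np.vstack([a.dosage(loci) for a in animals])


def sample_base(
    founder: FounderOutput,
    n_males: int,
    n_females: int,
    rng: np.random.Generator,
    population: Population | None = None,
) -> tuple[Population, list[Individual]]:
    """Sample the base population from the founder chromosome pools.

    For each animal and each chromosome, two copies are drawn without
    replacement from that chromosome's pool and restored before the next
    animal; chromosomes combine independently across pools.  Returns the
    population container and the list of base animals (males first).
    """
    spec = founder.spec
    n_pool = founder.n_haplotypes
    if n_pool < 2:
        raise ValueError("each chromosome pool must hold at least two haplotypes")
    pop = population if population is not None else Population()
    trait = founder.trait
    base: list[Individual] = []
    for k in range(n_males + n_females):
        parts0, parts1 = [], []
        for c in range(spec.n_chromosomes):
            i0, i1 = rng.choice(n_pool, size=2, replace=False)
            parts0.append(founder.pools[c][i0])
            parts1.append(founder.pools[c][i1])
        h0 = np.concatenate(parts0) if parts0 else np.empty(0, dtype=np.int64)
        h1 = np.concatenate(parts1) if parts1 else np.empty(0, dtype=np.int64)
        ind = Individual(
            id=pop.new_id(),
            sex=MALE if k < n_males else FEMALE,
            sire=None,
            dam=None,
            generation=0,
            hap=(h0, h1),
            tbv=compute_tbv((h0, h1), trait),
            phenotype=None,  # base animals are genotyped but not phenotyped
        )
        pop.add(ind)
        base.append(ind)
    return pop, base


def assign_ibd_alleles(base: list[Individual], spec: GenomeSpec) -> None:
    """Give the 2n base haplotypes 2n distinct labels at every IBD locus.

    Haplotype k of base animal i carries label 2*i + k uniformly across all
    tracer loci; labels are inherited through meiosis exactly like other loci
    and never enter any relationship matrix or GEBV.
    """
    d = spec.n_ibd_loci
    for i, ind in enumerate(base):
        ind.ibd = (
            np.full(d, 2 * i, dtype=np.int32),
            np.full(d, 2 * i + 1, dtype=np.int32),
        )


def make_offspring(
    pop: Population,
    sire: Individual,
    dam: Individual,
    sex: str,
    generation: int,
    spec: GenomeSpec,
    trait: TraitModel,
    rng: np.random.Generator,
) -> Individual:
    """Produce one offspring by meiosis in both parents (no new mutation
    during the breeding-scheme phase; the segregating locus set is frozen at
    the base population)."""
    g_s, ibd_s = recombine(spec, sire.hap, rng, ibd=sire.ibd)
    g_d, ibd_d = recombine(spec, dam.hap, rng, ibd=dam.ibd)
    ind = Individual(
        id=pop.new_id(),
        sex=sex,
        sire=sire.id,
        dam=dam.id,
        generation=generation,
        hap=(g_s, g_d),
        ibd=(ibd_s, ibd_d),
        tbv=compute_tbv((g_s, g_d), trait),
    )
    pop.add(ind)
    return ind
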