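"""Genome geometry: chromosomes, candidate loci, IBD tracer loci.

The simulated genome is a set of equally long chromosomes carrying a dense,
equidistant grid of candidate bi-allelic loci.  A fixed fraction of candidate
loci belongs to the QTL class (causal for the trait once mutated), the rest
are neutral markers.  A second, much sparser grid of "IBD tracer" loci is used
only to measure identity-by-descent relative to the base population; tracer
loci recombine with everything else but never enter any relationship matrix.

Because loci are equidistant, locus positions and the mapping from a genetic
interval to a contiguous range of locus identifiers are computed
arithmetically; no per-locus position array is ever materialised (the
full-scale genome has 3.006e7 candidate loci).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GenomeSpec"]


@dataclass(frozen=True)
class GenomeSpec:
    """Layout and mutation parameters of the simulated genome.

    Parameters
    ----------
    n_chromosomes:
        Number of chromosomes, all of equal genetic length.
    chrom_length_cM:
        Genetic length of each chromosome in centimorgan.
    loci_per_cM:
        Density of candidate (marker + QTL class) loci per centimorgan.
    qtl_fraction:
        Fraction of candidate loci belonging to the QTL class.
    mutation_rate:
        Per-locus, per-gamete probability that a currently monomorphic locus
        acquires the derived allele.
    ibd_loci_per_cM:
        Density of IBD tracer loci per centimorgan.
    """

    n_chromosomes: int = 18
    chrom_length_cM: float = 167.0
    loci_per_cM: float = 1.0e4
    qtl_fraction: float = 1.0 / 8.0
    mutation_rate: float = 4.0e-6
    ibd_loci_per_cM: float = 4.0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if self.chrom_length_cM <= 0 or self.loci_per_cM <= 0:
            raise ValueError("chromosome length and locus density must be positive")
        if not 0.0 < self.qtl_fraction < 1.0:
            raise ValueError("qtl_fraction must lie in (0, 1)")
        if self.mutation_rate < 0:
            raise ValueError("mutation rate must be non-negative")
        if self.ibd_loci_per_cM <= 0:
            raise ValueError("IBD locus density must be positive")

    # ---- scalar geometry -------------------------------------------------

    @property
    def loci_per_chrom(self) -> int:
        return int(round(self.chrom_length_cM * self.loci_per_cM))

    @property
    def n_loci(self) -> int:
        """Total number of candidate loci across the genome."""
        return self.n_chromosomes * self.loci_per_chrom

    @property
    def n_qtl_class_loci(self) -> float:
        """Expected number of candidate loci in the QTL class."""
        return self.n_loci * self.qtl_fraction

    @property
    def spacing_cM(self) -> float:
        return self.chrom_length_cM / self.loci_per_chrom

    @property
    def total_cM(self) -> float:
        return self.n_chromosomes * self.chrom_length_cM

    @property
    def length_morgans(self) -> float:
        """Genome length in Morgans; the mean crossover count per meiosis."""
        return self.total_cM / 100.0

    @property
    def ibd_per_chrom(self) -> int:
        return int(round(self.chrom_length_cM * self.ibd_loci_per_cM))

    @property
    def n_ibd_loci(self) -> int:
        return self.n_chromosomes * self.ibd_per_chrom

    @property
    def ibd_spacing_cM(self) -> float:
        return self.chrom_length_cM / self.ibd_per_chrom

    # ---- locus arithmetic ------------------------------------------------

    def locus_chrom(self, loci) -> np.ndarray:
        """Chromosome index (0-based) of each candidate locus id."""
        return np.asarray(loci, dtype=np.int64) // self.loci_per_chrom

    def locus_pos_cM(self, loci) -> np.ndarray:
        """Position within the chromosome, in cM (grid midpoints)."""
        local = np.asarray(loci, dtype=np.int64) % self.loci_per_chrom
        return (local + 0.5) * self.spacing_cM

    def locus_pos_global_cM(self, loci) -> np.ndarray:
        """Position on the concatenated genome axis, in cM."""
        loci = np.asarray(loci, dtype=np.int64)
        return self.locus_chrom(loci) * self.chrom_length_cM + self.locus_pos_cM(loci)

    def n_loci_below(self, x_cM: float) -> int:
        """Number of candidate loci with global position strictly below ``x_cM``."""
        return int(self._grid_below(x_cM, self.loci_per_chrom, self.spacing_cM))

    def n_ibd_below(self, x_cM: float) -> int:
        """Number of IBD tracer loci with global position strictly below ``x_cM``."""
        return int(self._grid_below(x_cM, self.ibd_per_chrom, self.ibd_spacing_cM))

    def _grid_below(self, x: float, per_chrom: int, spacing: float) -> int:
        if x <= 0:
            return 0
        c = min(int(x // self.chrom_length_cM), self.n_chromosomes - 1)
        local = x - c * self.chrom_length_cM
        k = int(np.ceil(local / spacing - 0.5))
        k = min(max(k, 0), per_chrom)
        return c * per_chrom + k

    def ibd_pos_global_cM(self) -> np.ndarray:
        """Global positions of all IBD tracer loci (midpoints of a uniform grid)."""
        local = (np.arange(self.ibd_per_chrom) + 0.5) * self.ibd_spacing_cM
        offsets = np.arange(self.n_chromosomes) * self.chrom_length_cM
        return (offsets[:, None] + local[None, :]).ravel()

    # ---- presets ---------------------------------------------------------

    @classmethod
    def full_scale(cls) -> "GenomeSpec":
        """The pig-like genome of the full-scale study: 18 x 167 cM,
        1e4 loci/cM, QTL:marker 1:7, mu = 4e-6, 4 IBD loci/cM."""
        return cls()

    @classmethod
    def reduced(cls) -> "GenomeSpec":
        """Desk-scale genome preserving all structural ratios except size:
        2 x 100 cM chromosomes, 100 candidate loci/cM, mu = 4e-5 (raised so
        mutation-drift equilibrium carries a useful number of segregating
        loci), 1 IBD tracer locus/cM."""
        return cls(
            n_chromosomes=2,
            chrom_length_cM=100.0,
            loci_per_cM=100.0,
            qtl_fraction=1.0 / 8.0,
            mutation_rate=4.0e-5,
            ibd_loci_per_cM=1.0,
        )
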