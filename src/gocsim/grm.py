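"""Genomic relationship matrices (VanRaden method 2).

G = W D^-1 W' / L, where W holds genotype dosages centred by twice the
base-population allele frequency, D is diagonal with entries 2 p_i (1 - p_i),
and L is the number of loci used.  Base frequencies are computed once from
the base population and frozen for the entire breeding scheme; loci
monomorphic in the base (p in {0, 1}) are excluded from W, D and L, since
D^-1 is undefined there.  Centring and the 2p(1-p) scale are invariant to
which allele is labelled minor, so derived-allele frequencies are used
throughout.

Matrices can be built from markers (source "M"), the trait QTL ("Q"), or
their union ("A").  ``GRMBuilder`` grows a matrix incrementally as new
generations are genotyped; the result is identical (to 1e-12) to recomputing
from the concatenated dosage matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RelationshipMatrix", "compute_grm", "select_loci", "extend_grm", "GRMBuilder"]


@dataclass
class RelationshipMatrix:
    """Symmetric genomic relationship matrix over an ordered animal list."""

    animal_ids: np.ndarray
    values: np.ndarray
    source: str  # "M", "Q" or "A"
    base_freqs: np.ndarray  # per retained locus, base-population derived-allele freq
    loci: np.ndarray  # retained locus ids, order matching base_freqs
    _x: np.ndarray | None = field(default=None, repr=False)  # scaled centred dosages

    @property
    def n_loci_used(self) -> int:
        return int(self.loci.size)

    def index_of(self, animal_ids) -> np.ndarray:
        order = {int(a): i for i, a in enumerate(self.animal_ids)}
        try:
            return np.array([order[int(a)] for a in animal_ids], dtype=np.int64)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"animal {e} not in relationship matrix") from e

    def submatrix(self, animal_ids) -> np.ndarray:
        idx = self.index_of(animal_ids)
        return self.values[np.ix_(idx, idx)]


def _validate_dosages(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d)
    if d.ndim != 2:
        raise ValueError("dosage matrix must be 2-D (animals x loci)")
    if d.size and (d.min() < 0 or d.max() > 2 or np.any(d != np.round(d))):
        raise ValueError("dosages must be integers in {0, 1, 2}")
    return d.astype(np.float64)


def _scaled_rows(d: np.ndarray, p: np.ndarray, L: int) -> np.ndarray:
    """Rows of W D^{-1/2} / sqrt(L): G is then the plain Gram matrix."""
    w = d - 2.0 * p
    return w / np.sqrt(2.0 * p * (1.0 - p) * L)


def compute_grm(
    dosages: np.ndarray,
    base_freqs: np.ndarray,
    source: str = "M",
    animal_ids=None,
    loci=None,
) -> RelationshipMatrix:
    """VanRaden method-2 relationship matrix from a dosage matrix.

    ``base_freqs`` are the base-population derived-allele frequencies of the
    columns; columns with frequency 0 or 1 are dropped and L reduced
    accordingly.
    """
    d = _validate_dosages(dosages)
    p = np.asarray(base_freqs, dtype=float)
    if p.size != d.shape[1]:
        raise ValueError("one base frequency per locus required")
    loci = np.arange(p.size, dtype=np.int64) if loci is None else np.asarray(loci, np.int64)
    keep = (p > 0.0) & (p < 1.0)
    if not keep.any():
        raise ValueError("all loci are monomorphic in the base population")
    p, d, loci = p[keep], d[:, keep], loci[keep]
    x = _scaled_rows(d, p, int(p.size))
    g = x @ x.T
    ids = (
        np.arange(d.shape[0], dtype=np.int64)
        if animal_ids is None
        else np.asarray(animal_ids, dtype=np.int64)
    )
    return RelationshipMatrix(ids, g, source, p, loci, _x=x)


def extend_grm(existing: RelationshipMatrix, new_ids, new_dosages) -> RelationshipMatrix:
    """Append animals to an existing matrix; identical (to 1e-12) to a full
    recompute on the concatenated dosage matrix.  ``new_dosages`` columns
    must correspond to the matrix's retained loci, in order."""
    if existing._x is None:
        raise ValueError("matrix does not carry genotype rows; cannot extend")
    d = _validate_dosages(new_dosages)
    if d.shape[1] != existing.n_loci_used:
        raise ValueError(
            f"locus mismatch: matrix uses {existing.n_loci_used} loci, "
            f"got {d.shape[1]} columns"
        )
    if d.shape[0] == 0:
        return existing
    x_new = _scaled_rows(d, existing.base_freqs, existing.n_loci_used)
    cross = existing._x @ x_new.T
    corner = x_new @ x_new.T
    values = np.block([[existing.values, cross], [cross.T, corner]])
    ids = np.concatenate([existing.animal_ids, np.asarray(new_ids, dtype=np.int64)])
    x = np.vstack([existing._x, x_new])
    return RelationshipMatrix(
        ids, values, existing.source, existing.base_freqs, existing.loci, _x=x
    )


def select_loci(table: pd.DataFrame, source: str, trait_qtl_ids=None) -> np.ndarray:
    """Locus ids entering a relationship matrix.

    "M": marker-class segregating loci.  "Q": the trait-model QTL subset
    (QTL dropped by architecture subsampling are excluded everywhere).
    "A": union of the two.  Ordering is by locus id, i.e. (chromosome,
    position).
    """
    if len(table) == 0:
        raise ValueError("segregating-locus table is empty")
    markers = table.loc[table["klass"] == "M", "locus"].to_numpy(dtype=np.int64)
    if source == "M":
        out = np.sort(markers)
    elif source == "Q":
        if trait_qtl_ids is None:
            raise ValueError("source 'Q' requires the trait QTL list")
        out = np.sort(np.asarray(trait_qtl_ids, dtype=np.int64))
    elif source == "A":
        if trait_qtl_ids is None:
            raise ValueError("source 'A' requires the trait QTL list")
        out = np.union1d(markers, np.asarray(trait_qtl_ids, dtype=np.int64))
    else:
        raise ValueError(f"unknown source {source!r}; expected 'M', 'Q' or 'A'")
    if out.size == 0:
        raise ValueError(f"locus selection for source {source!r} is empty")
    return out


class GRMBuilder:
    """Incrementally grown relationship matrix for one locus source.

    Base frequencies are fixed at construction from the base-population
    dosages; animals are appended generation by generation.
    """

    def __init__(self, loci: np.ndarray, source: str):
        self.source = source
        self.loci_all = np.asarray(loci, dtype=np.int64)
        self._matrix: RelationshipMatrix | None = None

    def initialise(self, base_ids, base_dosages) -> None:
        """Fix base frequencies from the base dosage matrix and add the base
        animals."""
        d = _validate_dosages(base_dosages)
        p = d.mean(axis=0) / 2.0
        self._matrix = compute_grm(
            d, p, source=self.source, animal_ids=base_ids, loci=self.loci_all
        )

    @property
    def matrix(self) -> RelationshipMatrix:
        if self._matrix is None:
            raise RuntimeError("builder not initialised with base animals")
        return self._matrix

    @property
    def loci_used(self) -> np.ndarray:
        return self.matrix.loci

    def add_animals(self, ids, dosages_all_loci) -> None:
        """Append animals; ``dosages_all_loci`` columns follow ``loci_all``
        and are reduced here to the retained (base-polymorphic) loci."""
        keep = np.isin(self.loci_all, self.matrix.loci)
        self._matrix = extend_grm(self.matrix, ids, np.asarray(dosages_all_loci)[:, keep])
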