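"""G-BLUP prediction of breeding values.

Model: y = 1 mu + Z g + e, with Var(g) = G sigma_g^2 over all genotyped
animals (phenotyped or not) and Var(e) = I sigma_e^2.  Variance components
are treated as known (the simulation's true values sigma_g^2 = 1,
sigma_e^2 = 4 by default, giving h^2 = 0.2).

The solver works in the observed-data form: with O the recorded animals,
V = sigma_g^2 G_OO + sigma_e^2 I is always positive definite, so the fit
tolerates a singular G (e.g. a QTL-based matrix of low rank).  mu_hat is the
GLS mean and g_hat = sigma_g^2 G[:, O] V^{-1} (y - 1 mu_hat) — the BLUP
conditional mean, defined for every animal in the matrix, with or without a
record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .grm import RelationshipMatrix

__all__ = ["GBLUPFit", "fit_gblup", "accuracy"]


@dataclass
class GBLUPFit:
    """GEBVs in the animal order of the relationship matrix used to fit."""

    mu_hat: float
    gebv: np.ndarray
    animal_ids: np.ndarray
    sigma_g2: float
    sigma_e2: float

    def gebv_of(self, animal_ids) -> np.ndarray:
        order = {int(a): i for i, a in enumerate(self.animal_ids)}
        return self.gebv[[order[int(a)] for a in animal_ids]]


def fit_gblup(
    records: list[tuple[int, float]],
    G: RelationshipMatrix,
    sigma_g2: float = 1.0,
    sigma_e2: float = 4.0,
) -> GBLUPFit:
    """Solve the mixed model for (mu_hat, g_hat) given phenotype records.

    ``records`` is a list of (animal id, phenotype); every recorded animal
    must appear in ``G``.  All animals in ``G`` receive a GEBV.
    """
    if len(records) == 0:
        raise ValueError("no phenotype records")
    if sigma_g2 <= 0 or sigma_e2 <= 0:
        raise ValueError("variance components must be positive")
    rec_ids = np.array([r[0] for r in records], dtype=np.int64)
    y = np.array([r[1] for r in records], dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite phenotypes in records")

    obs = G.index_of(rec_ids)
    g_oo = G.values[np.ix_(obs, obs)]
    v = sigma_g2 * g_oo + sigma_e2 * np.eye(obs.size)
    c, low = cho_factor(v, check_finite=False)
    ones = np.ones(obs.size)
    vi_1 = cho_solve((c, low), ones, check_finite=False)
    vi_y = cho_solve((c, low), y, check_finite=False)
    mu = float(ones @ vi_y) / float(ones @ vi_1)
    r = cho_solve((c, low), y - mu, check_finite=False)
    gebv = sigma_g2 * (G.values[:, obs] @ r)
    return GBLUPFit(mu, gebv, np.asarray(G.animal_ids), sigma_g2, sigma_e2)


def accuracy(gebv: np.ndarray, tbv: np.ndarray) -> float:
    """Pearson correlation between predictions and true breeding values.

    Returns NaN with a warning if the predictions have zero variance in the
    group (instead of crashing on a degenerate correlation).
    """
    gebv = np.asarray(gebv, dtype=float)
    tbv = np.asarray(tbv, dtype=float)
    if gebv.size == 0:
        raise ValueError("empty group")
    if np.var(tbv) <= 0:
        raise ValueError("TBV variance in the group is zero")
    if np.var(gebv) <= 0:
        warnings.warn("GEBV variance is zero in the group; accuracy undefined")
        return float("nan")
    return float(np.corrcoef(gebv, tbv)[0, 1])
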