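"""Summary statistics: rates of gain and inbreeding, accuracies, aggregation.

Rates of genetic gain are OLS slopes of the mean true breeding value of
animals born in generation t on t over the selection span.  Rates of
inbreeding (true, from IBD tracer loci, or pedigree-based) are
1 - exp(beta), with beta the OLS slope of ln(1 - F_t) on t, which inverts
the geometric decay of non-inbred genome exactly.  Pedigree inbreeding is
Wright's coefficient relative to the base, computed by the tabular
relationship method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ReplicateSummary",
    "true_inbreeding",
    "pedigree_inbreeding",
    "rate_of_gain",
    "rate_of_inbreeding",
    "aggregate",
    "gain_advantage_pct",
    "advantage_bounds_pct",
]


@dataclass
class ReplicateSummary:
    """Headline metrics of one scheme replicate."""

    dG: float
    dF_true: float
    dF_ped: float
    accuracy_male: float
    accuracy_female: float
    records: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    def as_row(self) -> dict:
        return {
            "dG": self.dG,
            "dF_true": self.dF_true,
            "dF_ped": self.dF_ped,
            "accuracy_male": self.accuracy_male,
            "accuracy_female": self.accuracy_female,
        }


def true_inbreeding(ibd_pair) -> float:
    """Fraction of IBD tracer loci at which the two allele labels coincide."""
    a, b = ibd_pair
    if a.size == 0:
        raise ValueError("individual carries no IBD tracer labels")
    return float(np.mean(a == b))


def pedigree_inbreeding(pedigree: dict) -> dict:
    """Wright's inbreeding coefficient for every animal in a pedigree.

    ``pedigree`` maps child id -> (sire id or None, dam id or None); base
    animals have (None, None) and coefficient 0.  Implemented with the
    tabular relationship method in a topological (parents-first) order;
    a cyclic pedigree raises.
    """
    order = _topological(pedigree)
    idx = {a: i for i, a in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n), dtype=np.float64)
    F: dict = {}
    for a in order:
        i = idx[a]
        s, d = pedigree[a]
        si = idx[s] if s is not None else None
        di = idx[d] if d is not None else None
        row = np.zeros(n)
        if si is not None:
            row += 0.5 * A[si]
        if di is not None:
            row += 0.5 * A[di]
        A[i, :i] = row[:i]
        A[:i, i] = row[:i]
        f = 0.5 * A[si, di] if (si is not None and di is not None) else 0.0
        A[i, i] = 1.0 + f
        F[a] = float(f)
    return F


def _topological(pedigree: dict) -> list:
    seen: dict = {}
    order: list = []

    def visit(a, stack):
        state = seen.get(a)
        if state == 2:
            return
        if state == 1:
            raise ValueError("pedigree contains a cycle")
        seen[a] = 1
        s, d = pedigree.get(a, (None, None))
        for p in (s, d):
            if p is not None:
                if p not in pedigree:
                    raise ValueError(f"parent {p} missing from pedigree")
                visit(p, stack)
        seen[a] = 2
        order.append(a)

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * len(pedigree) + 100))
    try:
        for a in pedigree:
            visit(a, [])
    finally:
        sys.setrecursionlimit(old)
    return order


def rate_of_gain(generations, mean_tbv) -> float:
    """OLS slope of mean TBV on generation number."""
    t = np.asarray(generations, dtype=float)
    g = np.asarray(mean_tbv, dtype=float)
    if t.size < 3:
        raise ValueError("need at least three generations for a slope")
    return float(np.polyfit(t, g, 1)[0])


def rate_of_inbreeding(generations, mean_F) -> float:
    """1 - exp(slope of ln(1 - F_t) on t); exact on geometric F series."""
    t = np.asarray(generations, dtype=float)
    f = np.asarray(mean_F, dtype=float)
    if t.size < 3:
        raise ValueError("need at least three generations for a slope")
    if np.any(f >= 1.0):
        raise ValueError("F_t = 1 encountered; log(1 - F) undefined")
    beta = np.polyfit(t, np.log(1.0 - f), 1)[0]
    return float(1.0 - np.exp(beta))


def aggregate(replicates: list[ReplicateSummary]) -> pd.DataFrame:
    """Mean and standard error of the replicate mean for each metric."""
    if len(replicates) < 2:
        raise ValueError("need at least two replicates to aggregate")
    df = pd.DataFrame([r.as_row() for r in replicates])
    out = pd.DataFrame(
        {"mean": df.mean(), "se": df.std(ddof=1) / np.sqrt(len(df))}
    )
    out.index.name = "metric"
    return out


# ---------------------------------------------------------------------------
# published-table style comparisons


def gain_advantage_pct(table: pd.DataFrame, focal: str, reference: str, column: str) -> float:
    """Percent advantage of scenario ``focal`` over ``reference`` in
    ``column`` of a scenario-indexed results table: 100*(a - b)/b."""
    a = float(table.loc[focal, column])
    b = float(table.loc[reference, column])
    return 100.0 * (a - b) / b


def advantage_bounds_pct(
    table: pd.DataFrame,
    focal: tuple = ("Q_M",),
    others: tuple | None = None,
    column: str = "dG",
) -> tuple[float, float]:
    """Min and max percent gain advantage of the focal scenarios over the
    comparison scenarios (default: every scenario not predicting with the
    QTL matrix)."""
    if others is None:
        others = [s for s in table.index if s not in focal and not s.startswith("Q")]
    advs = [gain_advantage_pct(table, f, o, column) for f in focal for o in others]
    return (min(advs), max(advs))
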