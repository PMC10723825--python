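"""Inclusion-based (co-)variable importance over the acceptable family.

``vi(j)`` is the proportion of acceptable subsets containing covariate
``j``; ``vi(j, l)`` the proportion containing both.  A covariate with
``vi(j) = 1`` is a *keystone*: it belongs to every near-optimal subset.
Large ``vi(j)`` and ``vi(l)`` with small ``vi(j, l)`` flags a redundant
pair — two covariates that are individually important yet interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .family import AcceptableFamily

__all__ = ["VIMatrix", "co_inclusion", "keystones", "joint_inclusion"]


@dataclass
class VIMatrix:
    """Symmetric co-inclusion proportions; diagonal = marginal inclusion."""

    values: np.ndarray  # (p+1) x (p+1), entries = count / family_size
    names: list[str]
    family_size: int

    def vi(self, j: int, l: int | None = None) -> float:
        return float(self.values[j, j if l is None else l])

    def marginal(self) -> pd.Series:
        """VI(j) sorted descending; exact rational counts over the family."""
        s = pd.Series(np.diag(self.values), index=self.names)
        return s.sort_values(ascending=False, kind="stable")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)


def co_inclusion(fam: AcceptableFamily, p: int, names=None) -> VIMatrix:
    """Co-inclusion proportion matrix over the family members.

    Entry ``(j, l)`` counts the members containing both ``j`` and ``l``,
    divided by the family size — an exact rational number.
    """
    if len(fam) == 0:
        raise ValueError("family is empty")
    p1 = p + 1
    ind = np.zeros((len(fam), p1))
    for r, s in enumerate(fam.members):
        ind[r, s.array] = 1.0
    counts = ind.T @ ind
    if names is None:
        names = [f"col{j}" for j in range(p1)]
    return VIMatrix(counts / len(fam), list(names), len(fam))


def joint_inclusion(fam: AcceptableFamily, indices: tuple[int, ...]) -> float:
    """n-way generalization: proportion of members containing every index."""
    idx = set(int(i) for i in indices)
    hits = sum(1 for s in fam.members if idx.issubset(s.indices))
    return hits / len(fam)


def keystones(vi: VIMatrix, tol: float = 0.0) -> list[str]:
    """Labels with marginal inclusion at least ``1 - tol``.

    ``tol = 0`` gives exact keystones (in every member); a small positive
    value reports covariates in "nearly all" members.
    """
    diag = np.diag(vi.values)
    return [vi.names[j] for j in range(len(diag)) if diag[j] >= 1.0 - tol]
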