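"""Posterior predictive uncertainty for subset coefficients.

The predictive action applies the optimal-action map to each posterior
predictive draw instead of the predictive mean: for squared error,
``delta~_S = (X_S' Omega X_S)^{-1} X_S' Omega y~`` per draw.  The
resulting coefficient draws carry a posterior predictive distribution and
give interval estimates for any subset, including data-selected ones.
The baseline "interval excludes zero" selector uses highest posterior
density intervals of the model coefficients themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .actions import Subset, WeightScheme
from .posterior import PosteriorDraws, PredictiveSummary

__all__ = [
    "PredictiveActionDraws",
    "predictive_actions",
    "interval_estimates",
    "hpd_interval",
    "hpd_select",
]


@dataclass
class PredictiveActionDraws:
    """Per-draw optimal coefficients for one subset (S x |S|)."""

    subset: Subset
    coef_draws: np.ndarray
    singular: bool = False

    @property
    def mean(self) -> np.ndarray:
        return self.coef_draws.mean(axis=0)


def predictive_actions(
    pred: PredictiveSummary, w: WeightScheme, s: Subset
) -> PredictiveActionDraws:
    """Weighted least squares of every predictive draw on the active columns.

    One factorization of the weighted Gram matrix is reused across draws;
    a singular Gram falls back to the minimum-norm pseudoinverse solution
    and is flagged.
    """
    Xs = pred.target.columns(s.array)
    sw = np.sqrt(w.omega)
    A = Xs * sw[:, None]
    B = pred.draws * sw[None, :]  # S x n
    G = A.T @ A
    singular = False
    try:
        cf = linalg.cho_factor(G)
        coef = linalg.cho_solve(cf, A.T @ B.T).T
    except linalg.LinAlgError:
        singular = True
        coef = (np.linalg.pinv(A) @ B.T).T
    return PredictiveActionDraws(s, coef, singular)


def interval_estimates(
    pad: PredictiveActionDraws, level: float = 0.90, p1: int | None = None
) -> pd.DataFrame:
    """Equal-tailed quantile intervals of the coefficient draws.

    Coefficients outside the subset are reported as exactly zero when the
    total column count ``p1`` is given.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    a = (1.0 - level) / 2.0
    lo = np.quantile(pad.coef_draws, a, axis=0)
    hi = np.quantile(pad.coef_draws, 1.0 - a, axis=0)
    point = pad.mean
    if p1 is None:
        idx = list(pad.subset.indices)
        in_subset = [True] * len(idx)
    else:
        idx = list(range(p1))
        dense = np.zeros((3, p1))
        cols = pad.subset.array
        dense[0, cols], dense[1, cols], dense[2, cols] = point, lo, hi
        point, lo, hi = dense
        in_subset = [j in pad.subset.indices for j in idx]
    return pd.DataFrame(
        {"index": idx, "point": point, "lo": lo, "hi": hi, "in_subset": in_subset}
    )


def hpd_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Shortest window containing ``level`` of the sorted draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    S = x.size
    m = max(int(np.ceil(level * S)), 2)
    if m >= S:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: S - m + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m - 1])


def hpd_select(
    fit: PosteriorDraws, level: float = 0.95, include_intercept: bool = False
) -> np.ndarray:
    """Baseline selector: indices whose HPD interval excludes zero.

    The intercept is tested like any other coefficient unless
    ``include_intercept`` forces it in.
    """
    selected = []
    for j in range(fit.n_columns):
        if j == 0 and include_intercept:
            selected.append(0)
            continue
        lo, hi = hpd_interval(fit.beta[:, j], level)
        if lo > 0 or hi < 0:
            selected.append(j)
    return np.asarray(selected, dtype=int)
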