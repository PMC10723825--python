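"""Optimal sparse linear actions under squared-error and cross-entropy loss.

Given fitted values from a Bayesian model, the loss-minimizing linear
coefficients for any covariate subset are a weighted least squares "fit to
the fit" (squared error), or a weighted logistic regression on the model's
predictive class probabilities (cross-entropy).  Classification search
additionally needs subset-invariant pseudo-data ``(z_hat, w_hat)`` derived
from the full-model probabilities, so that a single weighted-RSS criterion
can drive branch-and-bound enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .design import DesignMatrix
from .posterior import PredictiveSummary

__all__ = [
    "WeightScheme",
    "Subset",
    "LinearAction",
    "ClassPseudoData",
    "optimal_action_sq",
    "make_class_pseudodata",
    "optimal_action_ce",
]

EPS_CLIP = 1e-6  # probability clipping before the logit transform


@dataclass(frozen=True)
class WeightScheme:
    """Evaluation weights ``omega(x_i) > 0`` over the target rows."""

    omega: np.ndarray
    kind: str = "uniform"

    def __post_init__(self):
        object.__setattr__(self, "omega", np.asarray(self.omega, dtype=float))
        if np.any(self.omega <= 0):
            raise ValueError("weights must be strictly positive")

    @classmethod
    def uniform(cls, n: int) -> "WeightScheme":
        return cls(np.full(n, 1.0 / n), "uniform")

    @classmethod
    def kernel(
        cls, target: DesignMatrix, x_star: np.ndarray, ell: float
    ) -> "WeightScheme":
        """Locally-targeted weights ``omega_i ∝ exp(-||x_i - x*||^2 / ell)``."""
        if ell <= 0:
            raise ValueError("kernel range must be positive")
        x_star = np.asarray(x_star, dtype=float)
        d2 = np.sum((target.values[:, 1:] - x_star) ** 2, axis=1)
        w = np.exp(-d2 / ell)
        w = np.maximum(w, 1e-300)
        return cls(w / w.sum(), "kernel")


@dataclass(frozen=True, order=True)
class Subset:
    """A strictly increasing index set over the design columns (0 = intercept)."""

    indices: tuple[int, ...]

    def __post_init__(self):
        idx = tuple(int(i) for i in self.indices)
        object.__setattr__(self, "indices", idx)
        if len(idx) == 0:
            raise ValueError("subset must be non-empty")
        if any(i < 0 for i in idx):
            raise ValueError("negative column index")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("indices must be strictly increasing (no duplicates)")

    @classmethod
    def of(cls, *indices: int) -> "Subset":
        return cls(tuple(sorted(set(int(i) for i in indices))))

    def __len__(self) -> int:
        return len(self.indices)

    def __contains__(self, j: int) -> bool:
        return j in self.indices

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)


@dataclass
class LinearAction:
    """Optimal coefficients for a subset, with the in-sample loss constituent."""

    subset: Subset
    coef: np.ndarray  # on subset indices; zeros implied elsewhere
    loss_value: float
    singular: bool = False
    converged: bool = True

    def dense(self, p1: int) -> np.ndarray:
        out = np.zeros(p1)
        out[self.subset.array] = self.coef
        return out

    def to_record(self, names: list[str] | None = None) -> dict:
        rec = {
            "indices": list(self.subset.indices),
            "coef": [float(c) for c in self.coef],
            "loss": float(self.loss_value),
            "singular": bool(self.singular),
            "converged": bool(self.converged),
        }
        if names is not None:
            rec["names"] = [names[j] for j in self.subset.indices]
        return rec


def _wls(Xs: np.ndarray, y: np.ndarray, omega: np.ndarray):
    """Weighted least squares; minimum-norm solution when rank-deficient."""
    sw = np.sqrt(omega)
    A = Xs * sw[:, None]
    bvec = y * sw
    coef, _, rank, _ = np.linalg.lstsq(A, bvec, rcond=None)
    return coef, rank < Xs.shape[1]


def optimal_action_sq(
    target: DesignMatrix,
    yhat: np.ndarray,
    w: WeightScheme,
    s: Subset,
) -> LinearAction:
    """Optimal action under aggregate weighted squared-error loss.

    The coefficients are the weighted least squares fit of the model's
    fitted values ``yhat`` on the active columns; ``loss_value`` is the
    weighted residual sum of squares at the optimum.
    """
    yhat = np.asarray(yhat, dtype=float)
    Xs = target.columns(s.array)
    coef, singular = _wls(Xs, yhat, w.omega)
    resid = yhat - Xs @ coef
    loss = float(np.sum(w.omega * resid**2))
    return LinearAction(s, coef, loss, singular=singular)


@dataclass
class ClassPseudoData:
    """Subset-invariant pseudo-data for classification search.

    ``hhat`` are the model's predictive probabilities of the binary
    functional, ``zhat = logit(hhat)`` the working response, and
    ``what = omega * hhat * (1 - hhat)`` the working weights.
    """

    hhat: np.ndarray
    zhat: np.ndarray
    what: np.ndarray
    omega: np.ndarray
    threshold: float | None = None

    def __post_init__(self):
        if np.any(self.hhat <= 0) or np.any(self.hhat >= 1):
            raise ValueError("hhat must lie strictly inside (0, 1)")
        if np.any(self.what <= 0):
            raise ValueError("working weights must be positive")


def make_class_pseudodata(
    pred: PredictiveSummary,
    w: WeightScheme,
    threshold: float | None = None,
    eps_clip: float = EPS_CLIP,
) -> ClassPseudoData:
    """Build subset-invariant pseudo-data from predictive draws.

    With ``threshold=tau`` the binary functional is the exceedance
    indicator ``h(y~) = I{y~ >= tau}`` applied to continuous draws;
    without it the draws themselves must already be binary.  Probabilities
    are clipped to ``[eps_clip, 1 - eps_clip]`` before the logit.
    """
    if threshold is not None:
        h = (pred.draws >= threshold).astype(float)
    else:
        vals = np.unique(pred.draws)
        if not np.all(np.isin(vals, [0.0, 1.0])):
            raise ValueError("identity functional requires binary predictive draws")
        h = pred.draws
    hhat = np.clip(h.mean(axis=0), eps_clip, 1.0 - eps_clip)
    if np.all(hhat <= eps_clip) or np.all(hhat >= 1.0 - eps_clip):
        import warnings

        warnings.warn(
            "degenerate target: every predictive probability saturates the "
            "same way; the working response carries no contrast",
            RuntimeWarning,
        )
    zhat = special.logit(hhat)
    what = w.omega * hhat * (1.0 - hhat)
    return ClassPseudoData(hhat, zhat, what, w.omega, threshold)


def cross_entropy_loss(hhat, eta, omega) -> float:
    """Exact weighted cross-entropy of probabilities expit(eta) against hhat.

    Stable form: -sum omega * [hhat*log(pi) + (1-hhat)*log(1-pi)] >= 0.
    """
    # log(pi) = -log(1+e^-eta), log(1-pi) = -eta - log(1+e^-eta)
    lse = np.logaddexp(0.0, -eta)
    return float(np.sum(omega * (hhat * lse + (1.0 - hhat) * (eta + lse))))


def optimal_action_ce(
    target: DesignMatrix,
    pd_: ClassPseudoData,
    s: Subset,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LinearAction:
    """Optimal action under weighted cross-entropy via IRLS.

    The coefficients minimize the weighted cross-entropy of the continuous
    responses ``hhat``; ``loss_value`` is the exact cross-entropy at the
    optimum (not the quadratic IRLS surrogate).
    """
    Xs = target.columns(s.array)
    d = Xs.shape[1]
    coef = np.zeros(d)
    converged = False
    singular = False
    for _ in range(max_iter):
        eta = Xs @ coef
        pi = special.expit(eta)
        wt = pd_.omega * np.clip(pi * (1 - pi), 1e-10, None)
        z = eta + (pd_.hhat - pi) / np.clip(pi * (1 - pi), 1e-10, None)
        new, sing = _wls(Xs, z, wt)
        singular = singular or sing
        if np.max(np.abs(new - coef)) < tol:
            coef = new
            converged = True
            break
        coef = new
    if not converged:
        import warnings

        warnings.warn(
            f"IRLS did not converge within {max_iter} iterations for subset "
            f"{s.indices}; returning last iterate",
            RuntimeWarning,
        )
    loss = cross_entropy_loss(pd_.hhat, Xs @ coef, pd_.omega)
    return LinearAction(s, coef, loss, singular=singular, converged=converged)
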