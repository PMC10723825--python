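"""Out-of-sample evaluation and the acceptable family of near-optimal subsets.

Candidate subsets are compared on K-fold out-of-sample losses computed
*without refitting* the Bayesian model: the full-data posterior serves as
an importance-sampling proposal for each training-fold posterior, with
weights proportional to the reciprocal validation-fold likelihood.  Each
subset gets

* an empirical cross-validated loss (its training-fold action scored
  against the held-out responses), and
* a distribution of predictive out-of-sample losses (the same action
  scored against posterior predictive draws of the held-out data),

and the acceptable family collects every subset whose percent increase in
predictive loss over the empirically best subset stays within a margin
``eta`` with posterior predictive probability at least ``eps``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .actions import LinearAction, Subset, WeightScheme, _wls
from .design import DesignMatrix
from .posterior import PosteriorDraws, PredictiveSummary, pointwise_loglik
from .search import CandidateSet

__all__ = [
    "FoldPlan",
    "ISWeights",
    "SubsetOOS",
    "AcceptableFamily",
    "make_folds",
    "importance_weights",
    "train_fold_action",
    "oos_losses",
    "build_family",
    "family_no_cv",
]


@dataclass
class FoldPlan:
    """Random partition of ``1..n`` into K folds of near-equal size."""

    K: int
    assignments: np.ndarray
    seed: int

    def fold(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == k)

    def train(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != k)


def make_folds(n: int, K: int, seed: int = 0) -> FoldPlan:
    if not 2 <= K <= n:
        raise ValueError(f"need 2 <= K <= n, got K={K}, n={n}")
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % K
    rng.shuffle(labels)
    return FoldPlan(K, labels, seed)


@dataclass
class ISWeights:
    """Normalized importance weights per fold, with effective sample sizes.

    Row ``k`` reweights the full-data posterior draws toward the posterior
    that conditions only on the training folds: ``w_ks ∝ 1 / p(y_{I_k} |
    theta_s)``, computed in log space with max-subtraction.
    """

    weights: np.ndarray  # K x S, rows sum to 1
    ess: np.ndarray  # K

    def __post_init__(self):
        sums = self.weights.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError("weight rows must sum to one")


def importance_weights(
    fit: PosteriorDraws,
    X: DesignMatrix,
    y: np.ndarray,
    folds: FoldPlan,
    ess_min: float = 25.0,
    stabilize: str | None = None,
) -> ISWeights:
    """Per-fold importance weights with heavy-tail stabilization.

    Raw weights are the reciprocal validation-fold likelihoods, computed
    in log space with max-subtraction.  They can have heavy right tails;
    ``stabilize="truncate"`` optionally caps raw weights at
    ``mean * sqrt(S)`` (the standard truncated-IS rule, trading a small
    bias for variance reduction) before normalization.
    """
    ll = pointwise_loglik(fit, X, y)  # S x n
    S = ll.shape[0]
    W = np.empty((folds.K, S))
    ess = np.empty(folds.K)
    for k in range(folds.K):
        lw = -ll[:, folds.fold(k)].sum(axis=1)
        lw -= lw.max()
        w = np.exp(lw)
        if stabilize == "truncate":
            w = np.minimum(w, w.mean() * np.sqrt(S))
        elif stabilize is not None:
            raise ValueError(f"unknown stabilization {stabilize!r}")
        w /= w.sum()
        W[k] = w
        ess[k] = 1.0 / np.sum(w**2)
    if np.any(ess < ess_min):
        warnings.warn(
            f"minimum importance-sampling ESS {ess.min():.1f} < {ess_min}; "
            "consider increasing the number of posterior draws",
            RuntimeWarning,
        )
    return ISWeights(W, ess)


def _systematic_resample(w: np.ndarray, S: int, u: float) -> np.ndarray:
    """Systematic resampling: S indices with expected counts S*w.

    With uniform weights this returns each index exactly once.
    """
    positions = (np.arange(S) + u) / S
    return np.searchsorted(np.cumsum(w), positions).clip(max=len(w) - 1)


def resample_draw_indices(isw: ISWeights, seed: int = 0) -> np.ndarray:
    """Per-fold equal-weight draw indices (K x S), shared by all subsets.

    Resampling converts each fold's weighted sample of posterior draws into
    an unweighted one while keeping the draw index aligned across subsets,
    so loss differences are computed under common random numbers.
    """
    rng = np.random.default_rng(seed)
    K, S = isw.weights.shape
    return np.vstack(
        [_systematic_resample(isw.weights[k], S, rng.uniform()) for k in range(K)]
    )


@dataclass
class SubsetOOS:
    """Out-of-sample losses for one candidate subset."""

    subset: Subset
    emp_loss: float
    pred_loss_draws: np.ndarray  # length S, fold-averaged
    per_fold_emp: np.ndarray  # length K

    def __post_init__(self):
        if not np.all(np.isfinite(self.pred_loss_draws)):
            raise ValueError("predictive loss draws must be finite")


def train_fold_action(
    mufit: np.ndarray,
    X: DesignMatrix,
    w: WeightScheme,
    s: Subset,
    train_rows: np.ndarray,
    fold_weights: np.ndarray,
) -> LinearAction:
    """Optimal action from training-fold data only, squared-error loss.

    The training-fold pseudo-response is the importance-weighted posterior
    predictive mean ``sum_s w_ks E[y~_i | theta_s]`` on the training rows.
    """
    yhat_train = fold_weights @ mufit[:, train_rows]
    Xs = X.values[np.ix_(train_rows, s.array)]
    coef, singular = _wls(Xs, yhat_train, w.omega[train_rows])
    resid = yhat_train - Xs @ coef
    loss = float(np.sum(w.omega[train_rows] * resid**2))
    return LinearAction(s, coef, loss, singular=singular)


def _irls(Xs, h, omega, max_iter=100, tol=1e-8):
    coef = np.zeros(Xs.shape[1])
    for _ in range(max_iter):
        eta = Xs @ coef
        pi = special.expit(eta)
        v = np.clip(pi * (1 - pi), 1e-10, None)
        new, _ = _wls(Xs, eta + (h - pi) / v, omega * v)
        if np.max(np.abs(new - coef)) < tol:
            return new
        coef = new
    return coef


def _ce_vec(h, eta, axis=None):
    """Elementwise cross-entropy -[h log pi + (1-h) log(1-pi)], pi=expit(eta)."""
    lse = np.logaddexp(0.0, -eta)
    val = h * lse + (1.0 - h) * (eta + lse)
    return val if axis is None else val.mean(axis=axis)


def oos_losses(
    candidates: CandidateSet,
    fit: PosteriorDraws,
    X: DesignMatrix,
    y: np.ndarray,
    pred: PredictiveSummary,
    w: WeightScheme,
    folds: FoldPlan,
    isw: ISWeights,
    loss: str = "sq",
    threshold: float | None = None,
    resample_seed: int = 0,
) -> list[SubsetOOS]:
    """Empirical and predictive K-fold losses for every candidate subset.

    ``loss='sq'`` scores squared error against held-out responses and
    predictive draws; ``loss='ce'`` scores exact cross-entropy of the
    binary functional (the response itself, or the exceedance indicator
    ``I{y >= threshold}``).  Predictive losses use per-fold systematic
    resampling of the importance weights, with draw indices shared across
    subsets so that loss differences are coupled draw by draw.
    """
    y = np.asarray(y, dtype=float)
    subsets = candidates.subsets()
    S = fit.n_draws
    K = folds.K
    R = resample_draw_indices(isw, resample_seed)

    if loss == "sq":
        mufit = fit.beta @ X.values.T  # S x n, E[y~|theta]
        target_draws = pred.draws
        emp_target = y
    elif loss == "ce":
        if fit.is_gaussian and threshold is None:
            raise ValueError("cross-entropy with a Gaussian model needs a threshold")
        mu = fit.beta @ X.values.T
        mufit = None if fit.is_gaussian else special.expit(mu)
        if threshold is not None:
            target_draws = (pred.draws >= threshold).astype(float)
            emp_target = (y >= threshold).astype(float)
        else:
            target_draws = pred.draws
            emp_target = y
        # predictive probability of the functional, per draw and row
        if fit.is_gaussian:
            from scipy.stats import norm

            mufit = 1.0 - norm.cdf((threshold - mu) / fit.sigma[:, None])
        if np.unique(emp_target).size < 2:
            raise ValueError("degenerate binary target after thresholding")
    else:
        raise ValueError("loss must be 'sq' or 'ce'")

    out = []
    per_fold_cache = []
    for k in range(K):
        tr, va = folds.train(k), folds.fold(k)
        fw = isw.weights[k]
        if loss == "sq":
            ytr = fw @ mufit[:, tr]
        else:
            ytr = np.clip(fw @ mufit[:, tr], 1e-6, 1 - 1e-6)
        Vk = target_draws[R[k]][:, va]  # S x |va| resampled predictive draws
        per_fold_cache.append((tr, va, ytr, Vk))

    for s in subsets:
        emp_k = np.empty(K)
        pred_draws = np.zeros(S)
        for k in range(K):
            tr, va, ytr, Vk = per_fold_cache[k]
            Xtr = X.values[np.ix_(tr, s.array)]
            Xva = X.values[np.ix_(va, s.array)]
            if loss == "sq":
                coef, _ = _wls(Xtr, ytr, w.omega[tr])
                f = Xva @ coef
                emp_k[k] = np.mean((y[va] - f) ** 2)
                pred_draws += np.mean((Vk - f) ** 2, axis=1)
            else:
                coef = _irls(Xtr, ytr, w.omega[tr])
                eta_va = Xva @ coef
                emp_k[k] = float(np.mean(_ce_vec(emp_target[va], eta_va)))
                pred_draws += _ce_vec(Vk, eta_va[None, :], axis=1)
        pred_draws /= K
        out.append(SubsetOOS(s, float(emp_k.mean()), pred_draws, emp_k))
    return out


@dataclass
class AcceptableFamily:
    """Subsets within ``eta`` percent of the best subset's predictive loss
    with posterior predictive probability at least ``eps``."""

    members: list[Subset]
    eta: float
    eps: float
    s_min: Subset
    s_small: Subset
    prob_within: dict[tuple, float]
    emp_loss: dict[tuple, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, s: Subset) -> bool:
        return s in self.members

    def member_sizes(self) -> np.ndarray:
        return np.array([len(s) for s in self.members])

    def to_record(self) -> dict:
        return {
            "eta": self.eta,
            "eps": self.eps,
            "s_min": list(self.s_min.indices),
            "s_small": list(self.s_small.indices),
            "members": [
                {
                    "indices": list(s.indices),
                    "size": len(s),
                    "prob_within": self.prob_within[s.indices],
                    "emp_loss": self.emp_loss.get(s.indices),
                }
                for s in self.members
            ],
        }

    @classmethod
    def from_record(cls, rec: dict) -> "AcceptableFamily":
        members = [Subset(tuple(m["indices"])) for m in rec["members"]]
        return cls(
            members=members,
            eta=float(rec["eta"]),
            eps=float(rec["eps"]),
            s_min=Subset(tuple(rec["s_min"])),
            s_small=Subset(tuple(rec["s_small"])),
            prob_within={
                tuple(m["indices"]): float(m["prob_within"]) for m in rec["members"]
            },
            emp_loss={
                tuple(m["indices"]): m.get("emp_loss") for m in rec["members"]
            },
        )


def _pick_small(members, emp):
    """Smallest member; ties broken by smallest empirical loss."""
    min_size = min(len(s) for s in members)
    pool = [s for s in members if len(s) == min_size]
    return min(pool, key=lambda s: (emp[s.indices], s.indices))


def build_family(
    oos: list[SubsetOOS], eta: float = 0.0, eps: float = 0.10
) -> AcceptableFamily:
    """Acceptable family from out-of-sample losses.

    The anchor ``s_min`` minimizes the empirical K-fold loss.  Membership
    uses the non-strict comparison ``D~ <= eta`` so that the anchor itself
    is always acceptable (its percent increase is identically zero).
    """
    if not oos:
        raise ValueError("no candidate subsets to evaluate")
    i_min = int(np.argmin([o.emp_loss for o in oos]))
    anchor = oos[i_min]
    denom = anchor.pred_loss_draws
    if np.any(denom <= 0):
        raise FloatingPointError(
            "anchor predictive loss draws must be strictly positive"
        )
    members, prob_within, emp = [], {}, {}
    for o in oos:
        dtil = 100.0 * (o.pred_loss_draws - denom) / denom
        p = float(np.mean(dtil <= eta))
        prob_within[o.subset.indices] = p
        emp[o.subset.indices] = o.emp_loss
        if p >= eps:
            members.append(o.subset)
    s_min = anchor.subset
    s_small = _pick_small(members, emp)
    return AcceptableFamily(members, eta, eps, s_min, s_small, prob_within, emp)


def family_no_cv(
    candidates: CandidateSet,
    actions: dict[tuple, LinearAction],
    pred: PredictiveSummary,
    w: WeightScheme,
    eta: float = 0.0,
    eps: float = 0.10,
    loss: str = "sq",
    threshold: float | None = None,
) -> AcceptableFamily:
    """Acceptable family at new covariates with no held-out responses.

    Without responses there is no empirical loss, so the anchor is the
    full screened subset (for a linear model its point prediction is the
    posterior predictive expectation).  Losses are per-draw averages of
    ``L(y~_i, x_i' delta_S)`` over the target rows, with full-data actions.
    """
    subsets = candidates.subsets()
    anchor_subset = max(subsets, key=len)
    if loss == "ce" and threshold is not None:
        draws = (pred.draws >= threshold).astype(float)
    else:
        draws = pred.draws

    loss_draws = {}
    for s in subsets:
        f = pred.target.columns(s.array) @ actions[s.indices].coef
        if loss == "sq":
            loss_draws[s.indices] = np.mean((draws - f) ** 2, axis=1)
        else:
            loss_draws[s.indices] = _ce_vec(draws, f[None, :], axis=1)

    denom = loss_draws[anchor_subset.indices]
    if np.any(denom <= 0):
        raise FloatingPointError("anchor loss draws must be strictly positive")
    members, prob_within, mean_loss = [], {}, {}
    for s in subsets:
        dtil = 100.0 * (loss_draws[s.indices] - denom) / denom
        p = float(np.mean(dtil <= eta))
        prob_within[s.indices] = p
        mean_loss[s.indices] = float(loss_draws[s.indices].mean())
        if p >= eps:
            members.append(s)
    s_small = _pick_small(members, mean_loss)
    return AcceptableFamily(
        members, eta, eps, anchor_subset, s_small, prob_within, mean_loss
    )
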