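"""Synthetic study designs and the replication harness.

The generator produces sparse linear-signal data with AR(1)-correlated
Gaussian covariates: marginally standard normal columns with
``Cor(x_j, x_j') = rho^{|j-j'|}``, randomly permuted, an intercept of -1,
``p_star`` nonzero coefficients (half +1, half -1 with the extra one
positive) on randomly chosen columns, and Gaussian noise scaled so that
``sd(y*) / sigma = SNR`` with the realized sample standard deviation of
the noiseless signal ``y*``.

The harness runs the full pipeline per replicate and scores marginal
selection (TPR/TNR), within-family prediction error against ``y*``, and
interval width/coverage, plus a classical best-subset-by-AIC baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import search, uncertainty
from .actions import WeightScheme
from .design import DesignMatrix
from .model import SubsetSelection

__all__ = [
    "SimDesign",
    "gen_dataset",
    "run_replication",
    "run_study",
    "family_rmse_quantiles",
    "aggregate_selection",
    "classification_variant",
    "aic_best_subset",
]


@dataclass
class SimDesign:
    """Sparse linear-signal design with AR-correlated covariates."""

    n: int
    p: int
    snr: float
    p_star: int = 5
    rho: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if self.p_star > self.p:
            raise ValueError("p_star cannot exceed p")
        if self.snr <= 0:
            raise ValueError("snr must be positive")


def gen_dataset(d: SimDesign):
    """Generate one dataset; returns (DesignMatrix, y, truth dict).

    The truth record carries the full coefficient vector (index 0 =
    intercept), the active column indices, the noiseless signal ``y*``,
    and the realized noise scale.
    """
    rng = np.random.default_rng(d.seed)
    L = np.linalg.cholesky(d.rho ** np.abs(np.subtract.outer(np.arange(d.p), np.arange(d.p))))
    Xr = rng.standard_normal((d.n, d.p)) @ L.T
    Xr = Xr[:, rng.permutation(d.p)]
    support = rng.choice(d.p, size=d.p_star, replace=False)
    beta = np.zeros(d.p + 1)
    beta[0] = -1.0
    n_pos = int(np.ceil(d.p_star / 2))
    beta[support[:n_pos] + 1] = 1.0
    beta[support[n_pos:] + 1] = -1.0
    X = DesignMatrix.from_array(Xr, standardize=False)
    ystar = X.values @ beta
    sd_star = ystar.std(ddof=1)
    sigma = sd_star / d.snr if np.isfinite(d.snr) else 0.0
    y = ystar + sigma * rng.standard_normal(d.n)
    truth = {
        "beta": beta,
        "active": np.concatenate([[0], np.sort(support + 1)]),
        "ystar": ystar,
        "sigma": sigma,
    }
    return X, y, truth


def selection_rates(selected, active, p1: int):
    """TPR over active columns and TNR over inactive non-intercept columns."""
    sel = set(int(j) for j in selected)
    act = set(int(j) for j in active)
    inact = set(range(1, p1)) - act
    tpr = len(sel & act) / len(act)
    tnr = len(inact - sel) / len(inact) if inact else 1.0
    return tpr, tnr


def _lasso_entry_order(Xc: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Order in which covariates enter the lasso path (LARS)."""
    from sklearn.linear_model import lars_path

    _, active, _ = lars_path(
        Xc - Xc.mean(axis=0), y - y.mean(), method="lasso", return_path=False
    )
    order = list(dict.fromkeys(active))
    rest = [j for j in range(Xc.shape[1]) if j not in order]
    return np.array(order + rest, dtype=int)


def aic_best_subset(X: DesignMatrix, y: np.ndarray, s_max: int = 35):
    """Classical (unregularized) best-subset selection with AIC size choice.

    When p exceeds the screening cap, the candidate pool is the first
    ``s_max - 1`` covariates to enter the lasso path; the best subset of
    each size is then found on the data itself, and the size is chosen by
    Gaussian AIC ``n log(RSS/n) + 2k``.
    """
    n, p1 = X.values.shape
    cols = np.arange(p1)
    if p1 > s_max:
        order = _lasso_entry_order(X.values[:, 1:], y)
        keep = np.sort(order[: s_max - 1]) + 1
        cols = np.concatenate([[0], keep])
    w = WeightScheme.uniform(n)
    cfg = search.SearchConfig(m_k=1, s_max=min(s_max, n - 2))
    cs = search.branch_and_bound(X, y, w, cfg, columns=cols)
    best, best_aic = None, np.inf
    for k in sorted(cs.by_size):
        s, rss = cs.by_size[k][0]
        rss_raw = rss * n  # uniform weights 1/n
        aic = n * np.log(max(rss_raw, 1e-300) / n) + 2 * k
        if aic < best_aic:
            best, best_aic = s, aic
    coef = np.linalg.lstsq(X.columns(best.array), y, rcond=None)[0]
    return best, coef


def run_replication(
    d: SimDesign,
    n_save: int = 500,
    n_burn: int = 500,
    m_k: int = 15,
    s_max: int = 35,
    K: int = 10,
    eta: float = 0.0,
    eps: float = 0.10,
    hpd_level: float = 0.95,
    interval_level: float = 0.90,
    compute_intervals: bool = False,
    compute_aic_baseline: bool = False,
) -> dict:
    """One end-to-end replicate; returns a flat metrics record.

    All pipeline randomness derives from ``d.seed``.
    """
    X, y, truth = gen_dataset(d)
    model = SubsetSelection(y, X.values[:, 1:], standardize=False)
    res = model.fit(
        n_save=n_save,
        n_burn=n_burn,
        seed=d.seed,
        m_k=m_k,
        s_max=min(s_max, d.p + 1),
        K=K,
        eta=eta,
        eps=eps,
    )
    active = truth["active"]
    p1 = d.p + 1
    row: dict = {"seed": d.seed, "n": d.n, "p": d.p, "snr": d.snr}
    for which in ("s_small", "s_min", "hpd"):
        tpr, tnr = selection_rates(res.selected_indices(which), active, p1)
        row[f"tpr_{which}"] = tpr
        row[f"tnr_{which}"] = tnr
    row["size_s_small"] = len(res.s_small)
    row["size_s_min"] = len(res.s_min)
    row["family_size"] = len(res.family)
    row["selected_s_small"] = list(map(int, res.s_small.indices))
    row["selected_s_min"] = list(map(int, res.s_min.indices))

    # RMSE against the noiseless signal, per acceptable-family member
    ystar = truth["ystar"]
    member_rmse = []
    for s in res.family.members:
        f = res.predict(subset=s)
        member_rmse.append(float(np.sqrt(np.mean((f - ystar) ** 2))))
    row["member_rmse"] = member_rmse
    row["rmse_s_small"] = float(
        np.sqrt(np.mean((res.predict(subset=res.s_small) - ystar) ** 2))
    )
    row["rmse_s_min"] = float(
        np.sqrt(np.mean((res.predict(subset=res.s_min) - ystar) ** 2))
    )
    post_mean_fit = X.values @ res.posterior.mean
    row["rmse_post_mean"] = float(np.sqrt(np.mean((post_mean_fit - ystar) ** 2)))

    if compute_aic_baseline:
        s_aic, coef_aic = aic_best_subset(X, y, s_max=s_max)
        f = X.columns(s_aic.array) @ coef_aic
        row["rmse_aic_subset"] = float(np.sqrt(np.mean((f - ystar) ** 2)))
        tpr, tnr = selection_rates(s_aic.array, active, p1)
        row["tpr_aic_subset"], row["tnr_aic_subset"] = tpr, tnr

    if compute_intervals:
        beta_star = truth["beta"]
        tab = res.coef_table(subset=res.s_small, level=interval_level)
        cover = (tab["lo"].to_numpy() <= beta_star) & (
            beta_star <= tab["hi"].to_numpy()
        )
        row["cover_s_small"] = float(cover.mean())
        row["width_s_small"] = float(
            np.median(tab["hi"].to_numpy() - tab["lo"].to_numpy())
        )
        hpd = np.array(
            [
                uncertainty.hpd_interval(res.posterior.beta[:, j], interval_level)
                for j in range(p1)
            ]
        )
        cover_hpd = (hpd[:, 0] <= beta_star) & (beta_star <= hpd[:, 1])
        row["cover_hpd"] = float(cover_hpd.mean())
        row["width_hpd"] = float(np.median(hpd[:, 1] - hpd[:, 0]))
    return row


def run_study(
    n: int,
    p: int,
    snr: float,
    n_reps: int = 20,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Independent replicates with seeds spawned from a master seed."""
    child = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    rows = []
    for r in range(n_reps):
        d = SimDesign(n=n, p=p, snr=snr, seed=int(child[r]))
        rows.append(run_replication(d, **kwargs))
    return pd.DataFrame(rows)


def family_rmse_quantiles(
    rows: pd.DataFrame, q=(0.0, 0.25, 0.5, 0.75, 1.0)
) -> pd.Series:
    """Per-replicate quantiles of within-family RMSE, averaged over replicates."""
    out = {}
    for qq in q:
        vals = [np.quantile(r, qq) for r in rows["member_rmse"] if len(r) > 0]
        out[qq] = float(np.mean(vals))
    return pd.Series(out, name="mean_rmse")


def aggregate_selection(rows: pd.DataFrame) -> pd.DataFrame:
    """Mean TPR/TNR by selector, with Monte-Carlo standard errors."""
    methods = sorted(
        c[4:] for c in rows.columns if c.startswith("tpr_")
    )
    rec = []
    for m in methods:
        rec.append(
            {
                "method": m,
                "TPR": rows[f"tpr_{m}"].mean(),
                "TPR_se": rows[f"tpr_{m}"].std(ddof=1) / np.sqrt(len(rows)),
                "TNR": rows[f"tnr_{m}"].mean(),
                "TNR_se": rows[f"tnr_{m}"].std(ddof=1) / np.sqrt(len(rows)),
            }
        )
    return pd.DataFrame(rec).set_index("method")


def classification_variant(d: SimDesign, tau_quantile: float = 0.5):
    """Continuous design turned into a thresholded classification task.

    Returns ``(X, y, threshold, truth)`` where the binary functional is
    ``I{y >= threshold}`` at the requested quantile of the response.
    """
    X, y, truth = gen_dataset(d)
    tau = float(np.quantile(y, tau_quantile))
    b = (y >= tau).astype(float)
    if np.unique(b).size < 2:
        raise ValueError("degenerate class after thresholding")
    return X, y, tau, truth
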