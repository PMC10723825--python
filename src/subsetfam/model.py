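"""Model/Results front end for Bayesian decision-analytic subset selection.

``SubsetSelection`` wraps the full pipeline behind a statsmodels-style
interface: construct it from data (or from externally supplied posterior
coefficient draws), call :meth:`fit`, and read the acceptable family, key
subsets, variable importance, and coefficient intervals off the returned
:class:`SubsetSelectionResults`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import actions, family, importance, posterior, search, uncertainty
from .design import DesignMatrix

__all__ = ["SubsetSelection", "SubsetSelectionResults"]


class SubsetSelection:
    """Bayesian decision-analytic subset selection for linear prediction
    or classification.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Response: continuous for squared-error loss, binary (or continuous
        with a ``threshold``) for cross-entropy loss.
    exog : array-like, shape (n, p)
        Covariates, without an intercept column (one is added).
    loss : {'sq', 'ce'}
        Optimization and evaluation loss.
    threshold : float, optional
        With ``loss='ce'`` and a continuous response, classify the
        exceedance indicator ``I{y >= threshold}``.
    weights : WeightScheme, optional
        Evaluation weights over the observed rows; uniform by default.
    standardize : bool
        Center and scale continuous covariates to SD 0.5 before fitting.
    """

    def __init__(
        self,
        endog,
        exog,
        column_names=None,
        loss: str = "sq",
        threshold: float | None = None,
        weights: actions.WeightScheme | None = None,
        standardize: bool = True,
    ):
        self.endog = np.asarray(endog, dtype=float)
        self.design = DesignMatrix.from_array(
            exog, column_names, standardize=standardize
        )
        if self.endog.shape[0] != self.design.n:
            raise ValueError("endog and exog row counts differ")
        if loss not in ("sq", "ce"):
            raise ValueError("loss must be 'sq' or 'ce'")
        self.loss = loss
        self.threshold = threshold
        self.weights = weights or actions.WeightScheme.uniform(self.design.n)
        self._external_draws: posterior.PosteriorDraws | None = None

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, response: str, **kwargs
    ) -> "SubsetSelection":
        y = df[response].to_numpy(dtype=float)
        X = df.drop(columns=[response])
        return cls(y, X.to_numpy(dtype=float), list(X.columns), **kwargs)

    @classmethod
    def from_draws(
        cls, endog, exog, beta, sigma=None, column_names=None, **kwargs
    ) -> "SubsetSelection":
        """Plug in coefficient draws from any external Bayesian model."""
        kwargs.setdefault("standardize", False)
        m = cls(endog, exog, column_names, **kwargs)
        m._external_draws = posterior.PosteriorDraws(beta, sigma)
        if m._external_draws.n_columns != m.design.n_columns:
            raise ValueError("draw columns must match design columns")
        return m

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        n_save: int = 1000,
        n_burn: int = 1000,
        seed: int = 0,
        strategy: str = "bba",
        m_k: int = 15,
        s_max: int = 35,
        K: int = 10,
        eta: float = 0.0,
        eps: float = 0.10,
        ess_min: float = 25.0,
    ) -> "SubsetSelectionResults":
        """Run model fit, subset search, and acceptable-family construction.

        All randomness (sampler, predictive draws, folds, resampling) is
        derived from ``seed``.
        """
        ss = np.random.SeedSequence(seed)
        sub = [int(s) for s in ss.generate_state(4) % (2**31)]
        if self._external_draws is not None:
            fit = self._external_draws
        elif self.loss == "ce" and self.threshold is None:
            fit = posterior.fit_logistic(
                self.design, self.endog, n_save, n_burn, seed=sub[0]
            )
        else:
            fit = posterior.fit_horseshoe_lm(
                self.design, self.endog, n_save, n_burn, seed=sub[0]
            )
        pred = posterior.predictive_draws(fit, self.design, seed=sub[1])

        cols = search.screen_covariates(fit, self.design, s_max)
        cfg = search.SearchConfig(m_k=m_k, s_max=s_max, strategy=strategy)
        if self.loss == "sq":
            pseudo_y, sw = pred.fitted, self.weights
        else:
            pdata = actions.make_class_pseudodata(
                pred, self.weights, threshold=self.threshold
            )
            pseudo_y = pdata.zhat
            sw = actions.WeightScheme(pdata.what, "irls")
        candidates = search.search_candidates(
            self.design, pseudo_y, sw, cfg, columns=cols
        )

        folds = family.make_folds(self.design.n, K, seed=sub[2])
        isw = family.importance_weights(fit, self.design, self.endog, folds, ess_min)
        oos = family.oos_losses(
            candidates,
            fit,
            self.design,
            self.endog,
            pred,
            self.weights,
            folds,
            isw,
            loss=self.loss,
            threshold=self.threshold,
            resample_seed=sub[3],
        )
        fam = family.build_family(oos, eta=eta, eps=eps)

        # full-data optimal action for every candidate subset
        acts = {}
        for s in candidates.subsets():
            if self.loss == "sq":
                acts[s.indices] = actions.optimal_action_sq(
                    self.design, pred.fitted, self.weights, s
                )
            else:
                acts[s.indices] = actions.optimal_action_ce(self.design, pdata, s)

        vi = importance.co_inclusion(fam, self.design.p, self.design.column_names)
        return SubsetSelectionResults(
            self, fit, pred, cols, candidates, oos, fam, acts, vi
        )


class SubsetSelectionResults:
    """Fitted pipeline: posterior, candidates, acceptable family, summaries."""

    def __init__(self, model, fit, pred, screened, candidates, oos, fam, acts, vi):
        self.model = model
        self.posterior = fit
        self.predictive = pred
        self.screened_columns = screened
        self.candidates = candidates
        self.oos = oos
        self.family = fam
        self.actions = acts
        self.vi = vi

    # -- key subsets ------------------------------------------------------

    @property
    def s_min(self) -> actions.Subset:
        return self.family.s_min

    @property
    def s_small(self) -> actions.Subset:
        return self.family.s_small

    def selected_indices(self, which: str = "s_small") -> np.ndarray:
        if which in ("s_small", "s_min"):
            return getattr(self, which).array
        if which == "hpd":
            return uncertainty.hpd_select(self.posterior, 0.95)
        raise ValueError("which must be 's_small', 's_min' or 'hpd'")

    def keystone_covariates(self, tol: float = 0.0) -> list[str]:
        return importance.keystones(self.vi, tol)

    # -- coefficients and prediction -------------------------------------

    def predictive_action_draws(self, subset=None) -> uncertainty.PredictiveActionDraws:
        s = subset or self.s_small
        return uncertainty.predictive_actions(self.predictive, self.model.weights, s)

    def coef_table(self, subset=None, level: float = 0.90) -> pd.DataFrame:
        """Point estimates and predictive-action intervals, zeros outside."""
        s = subset or self.s_small
        pad = self.predictive_action_draws(s)
        tab = uncertainty.interval_estimates(pad, level, p1=self.model.design.n_columns)
        tab.insert(0, "name", self.model.design.column_names)
        act = self.actions.get(s.indices)
        if act is not None:
            tab["point"] = act.dense(self.model.design.n_columns)
        return tab

    def predict(self, exog=None, subset=None) -> np.ndarray:
        s = subset or self.s_small
        act = self.actions[s.indices]
        X = (
            self.model.design.values
            if exog is None
            else self.model.design.transform(exog)
        )
        return X[:, s.array] @ act.coef

    # -- summary ----------------------------------------------------------

    def summary(self) -> str:
        d = self.model.design
        fam = self.family
        lines = [
            "Bayesian decision-analytic subset selection",
            "=" * 60,
            f"Observations: {d.n}    Covariates: {d.p}    Loss: {self.model.loss}",
            f"Posterior draws: {self.posterior.n_draws}    "
            f"Screened columns: {len(self.screened_columns)}",
            f"Candidate subsets: {len(self.candidates)}    "
            f"Acceptable family (eta={fam.eta:g}%, eps={fam.eps:g}): {len(fam)}",
            f"S_min  size {len(self.s_min)}: "
            + ", ".join(d.column_names[j] for j in self.s_min.indices),
            f"S_small size {len(self.s_small)}: "
            + ", ".join(d.column_names[j] for j in self.s_small.indices),
            "Keystone covariates: "
            + (", ".join(self.keystone_covariates()) or "(none)"),
            "=" * 60,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<SubsetSelectionResults: {len(self.candidates)} candidates, "
            f"{len(self.family)} acceptable, |S_small|={len(self.s_small)}>"
        )
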