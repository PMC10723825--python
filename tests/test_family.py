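import numpy as np
import pytest

from subsetfam.actions import Subset, WeightScheme
from subsetfam.design import DesignMatrix
from subsetfam.family import (
    AcceptableFamily,
    FoldPlan,
    ISWeights,
    SubsetOOS,
    build_family,
    family_no_cv,
    importance_weights,
    make_folds,
    oos_losses,
    resample_draw_indices,
)
from subsetfam.posterior import PosteriorDraws, PredictiveSummary, predictive_draws
from subsetfam.search import CandidateSet, SearchConfig


class TestFolds:
    def test_loo_is_permutation(self):
        plan = make_folds(10, 10, seed=1)
        assert sorted(plan.assignments) == list(range(10))

    def test_equal_sizes(self):
        plan = make_folds(100, 10, seed=2)
        sizes = [len(plan.fold(k)) for k in range(10)]
        assert sizes == [10] * 10

    @pytest.mark.parametrize("n,K", [(17, 3), (23, 5), (40, 7)])
    def test_partition_property(self, n, K):
        plan = make_folds(n, K, seed=n + K)
        all_idx = np.concatenate([plan.fold(k) for k in range(K)])
        assert sorted(all_idx) == list(range(n))
        sizes = [len(plan.fold(k)) for k in range(K)]
        assert max(sizes) - min(sizes) <= 1

    def test_bad_K(self):
        with pytest.raises(ValueError):
            make_folds(5, 6, seed=0)


class TestImportanceWeights:
    def test_constant_likelihood_gives_uniform(self, small_design):
        # identical draws: the validation likelihood is draw-independent
        beta = np.tile([1.0, 0, 0, 0, 0, 0], (50, 1))
        fit = PosteriorDraws(beta, np.ones(50))
        y = small_design.values @ beta[0]
        plan = make_folds(small_design.n, 5, seed=3)
        isw = importance_weights(fit, small_design, y, plan)
        assert np.allclose(isw.weights, 1 / 50)
        assert np.allclose(isw.ess, 50)

    def test_conjugate_normal_mean_oracle(self):
        """IS-weighted posterior mean given a training fold matches the
        closed-form conjugate training posterior within Monte-Carlo error."""
        rng = np.random.default_rng(10)
        n, S = 40, 4000
        sigma = 1.0
        tau2 = 4.0  # prior variance of the mean
        y = rng.normal(1.5, sigma, n)
        # exact full-data posterior of mu: N(m_full, v_full)
        v_full = 1 / (n / sigma**2 + 1 / tau2)
        m_full = v_full * y.sum() / sigma**2
        draws = rng.normal(m_full, np.sqrt(v_full), S)
        X = DesignMatrix(np.ones((n, 1)), ["(Intercept)"])
        fit = PosteriorDraws(draws[:, None], np.full(S, sigma))
        plan = make_folds(n, 4, seed=4)
        isw = importance_weights(fit, X, y, plan)
        for k in range(plan.K):
            tr = plan.train(k)
            v_tr = 1 / (len(tr) / sigma**2 + 1 / tau2)
            m_tr = v_tr * y[tr].sum() / sigma**2
            is_mean = isw.weights[k] @ draws
            mc_se = np.sqrt(v_tr / isw.ess[k])
            assert abs(is_mean - m_tr) < 5 * mc_se + 0.02

    def test_low_ess_warns(self, small_design):
        rng = np.random.default_rng(5)
        beta = rng.standard_normal((30, 6)) * 3
        fit = PosteriorDraws(beta, np.full(30, 0.1))
        y = rng.standard_normal(small_design.n)
        plan = make_folds(small_design.n, 3, seed=6)
        with pytest.warns(RuntimeWarning, match="ESS"):
            importance_weights(fit, small_design, y, plan, ess_min=25)

    def test_normalization_exact(self, small_design, rng):
        beta = rng.standard_normal((60, 6))
        fit = PosteriorDraws(beta, np.ones(60))
        y = rng.standard_normal(small_design.n)
        plan = make_folds(small_design.n, 5, seed=7)
        isw = importance_weights(fit, small_design, y, plan)
        assert np.allclose(isw.weights.sum(axis=1), 1.0, atol=1e-12)


class TestResampling:
    def test_uniform_weights_identity(self):
        isw = ISWeights(np.full((2, 8), 1 / 8), np.full(2, 8.0))
        R = resample_draw_indices(isw, seed=0)
        assert np.array_equal(np.sort(R, axis=1), np.tile(np.arange(8), (2, 1)))

    def test_degenerate_weight_collapses(self):
        w = np.zeros((1, 10))
        w[0, 3] = 1.0
        isw = ISWeights(w, np.ones(1))
        R = resample_draw_indices(isw, seed=1)
        assert np.all(R == 3)


def _degenerate_pipeline(rng, n=16, S=60, sigma=0.4):
    """Small linear-truth pipeline whose pieces are easy to recompute."""
    Z = rng.standard_normal((n, 3))
    X = DesignMatrix.from_array(Z)
    beta = np.array([1.0, 2.0, 0.0, 0.0])
    y = X.values @ beta + sigma * rng.standard_normal(n)
    draws = beta + 0.05 * rng.standard_normal((S, 4))
    fit = PosteriorDraws(draws, np.full(S, sigma))
    pred = predictive_draws(fit, X, seed=0)
    return X, y, fit, pred


class TestOOSLosses:
    def test_hand_computed_intercept_only_two_folds(self):
        """4 points, K=2, uniform IS weights: fold losses by pencil."""
        n = 4
        X = DesignMatrix(np.ones((n, 1)), ["(Intercept)"])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        yhat = np.array([1.0, 2.0, 3.0, 4.0])
        S = 6
        beta = np.tile([[2.5]], (S, 1))  # constant draws -> uniform weights
        fit = PosteriorDraws(beta, np.ones(S))
        pred = PredictiveSummary(np.tile(yhat, (S, 1)), yhat, X)
        # but fitted of constant model is 2.5 at all rows; override pred:
        mu = np.full((S, n), 2.5)
        pred = PredictiveSummary(mu, mu.mean(axis=0), X)
        plan = FoldPlan(2, np.array([0, 0, 1, 1]), 0)
        isw = ISWeights(np.full((2, S), 1 / S), np.full(2, float(S)))
        cands = CandidateSet(
            {1: [(Subset((0,)), 0.0)]}, (0,), SearchConfig(m_k=1, s_max=1)
        )
        oos = oos_losses(
            cands, fit, X, y, pred, WeightScheme.uniform(n), plan, isw
        )
        # training action = mean of fitted (2.5) on training rows = 2.5
        # fold 0 validates on y=(1,2): mean((1-2.5)^2,(2-2.5)^2)=1.25
        # fold 1 validates on y=(3,4): mean((3-2.5)^2,(4-2.5)^2)=1.25
        assert np.isclose(oos[0].emp_loss, 1.25)
        assert np.allclose(oos[0].per_fold_emp, [1.25, 1.25])

    def test_perfect_predictor_zero_loss(self, rng):
        n = 12
        Z = rng.standard_normal((n, 2))
        X = DesignMatrix.from_array(Z)
        beta = np.array([0.5, 1.0, -1.0])
        y = X.values @ beta
        S = 40
        fit = PosteriorDraws(np.tile(beta, (S, 1)), np.full(S, 1e-8))
        pred = predictive_draws(fit, X, seed=1)
        plan = make_folds(n, 3, seed=2)
        isw = importance_weights(fit, X, y, plan)
        cands = CandidateSet(
            {3: [(Subset((0, 1, 2)), 0.0)]}, (0, 1, 2), SearchConfig(m_k=1, s_max=3)
        )
        oos = oos_losses(cands, fit, X, y, pred, WeightScheme.uniform(n), plan, isw)
        assert oos[0].emp_loss < 1e-12
        assert np.all(oos[0].pred_loss_draws < 1e-12)

    def test_predictive_loss_carries_noise_floor(self, rng):
        X, y, fit, pred = _degenerate_pipeline(rng, n=40, S=300, sigma=0.6)
        plan = make_folds(40, 5, seed=8)
        isw = importance_weights(fit, X, y, plan)
        cands = CandidateSet(
            {2: [(Subset((0, 1)), 0.0)]}, (0, 1, 2, 3), SearchConfig(m_k=1, s_max=2)
        )
        oos = oos_losses(cands, fit, X, y, pred, WeightScheme.uniform(40), plan, isw)
        # predictive loss includes the irreducible sigma^2 ~ 0.36
        assert oos[0].pred_loss_draws.mean() > 0.2


class TestBuildFamily:
    def _mk_oos(self, subset, emp, draws):
        return SubsetOOS(Subset(subset), emp, np.asarray(draws, float), np.array([emp]))

    def test_single_candidate(self):
        fam = build_family([self._mk_oos((0,), 1.0, [1.0, 1.1, 0.9])])
        assert fam.members == [Subset((0,))]
        assert fam.s_min == fam.s_small == Subset((0,))

    def test_eps_zero_admits_all(self):
        oos = [
            self._mk_oos((0,), 1.0, [1.0, 1.0]),
            self._mk_oos((0, 1), 0.9, [0.9, 0.9]),
            self._mk_oos((0, 2), 5.0, [5.0, 5.0]),
        ]
        fam = build_family(oos, eta=0.0, eps=0.0)
        assert len(fam) == 3

    def test_membership_matches_brute_force(self):
        """Two-subset fixture with a known draw-wise D-tilde distribution."""
        rng = np.random.default_rng(9)
        anchor_draws = rng.uniform(1.0, 2.0, 500)
        other_draws = anchor_draws * rng.uniform(0.9, 1.4, 500)
        oos = [
            self._mk_oos((0, 1), 1.0, anchor_draws),
            self._mk_oos((0, 2), 1.5, other_draws),
        ]
        dtil = 100 * (other_draws - anchor_draws) / anchor_draws
        p_brute = np.mean(dtil <= 5.0)
        fam = build_family(oos, eta=5.0, eps=0.10)
        assert np.isclose(fam.prob_within[(0, 2)], p_brute)
        assert (Subset((0, 2)) in fam.members) == (p_brute >= 0.10)

    def test_s_small_tie_broken_by_empirical_loss(self):
        oos = [
            self._mk_oos((0, 1), 1.0, [1.0, 1.0]),
            self._mk_oos((0, 2), 0.98, [1.0, 1.0]),
            self._mk_oos((0, 1, 2), 0.97, [0.97, 0.97]),
        ]
        fam = build_family(oos, eta=0.0, eps=0.0)
        assert fam.s_small == Subset((0, 2))

    def test_family_grows_with_eta_and_shrinks_with_eps(self):
        rng = np.random.default_rng(11)
        oos = [self._mk_oos((0,), 1.0, rng.uniform(0.8, 1.2, 200))]
        for j in range(1, 6):
            oos.append(
                self._mk_oos((0, j), 1.0 + 0.1 * j,
                             rng.uniform(0.8, 1.2, 200) + 0.05 * j)
            )
        sizes = []
        for eta in (0.0, 5.0, 20.0):
            sizes.append(len(build_family(oos, eta=eta, eps=0.10)))
        assert sizes == sorted(sizes)
        sizes_eps = []
        for eps in (0.5, 0.2, 0.0):
            sizes_eps.append(len(build_family(oos, eta=0.0, eps=eps)))
        assert sizes_eps == sorted(sizes_eps)

    def test_anchor_always_member(self):
        rng = np.random.default_rng(12)
        oos = [
            self._mk_oos((0, j), 1.0 + rng.uniform(), rng.uniform(0.5, 2.0, 100))
            for j in range(1, 5)
        ]
        fam = build_family(oos, eta=0.0, eps=0.10)
        assert fam.s_min in fam.members

    def test_round_trip_record(self):
        oos = [
            self._mk_oos((0,), 1.0, [1.0, 1.0]),
            self._mk_oos((0, 1), 0.9, [0.9, 0.9]),
        ]
        fam = build_family(oos)
        back = AcceptableFamily.from_record(fam.to_record())
        assert back.members == fam.members
        assert back.s_small == fam.s_small
        for m in fam.members:
            assert back.prob_within[m.indices] == fam.prob_within[m.indices]


class TestFamilyNoCV:
    def test_full_subset_always_member_and_brute_force(self, rng):
        from subsetfam.actions import optimal_action_sq

        X, y, fit, pred = _degenerate_pipeline(rng, n=20, S=100)
        w = WeightScheme.uniform(20)
        subsets = [Subset((0,)), Subset((0, 1)), Subset((0, 1, 2, 3))]
        cands = CandidateSet(
            {len(s.indices): [(s, 0.0)] for s in subsets},
            (0, 1, 2, 3),
            SearchConfig(m_k=1, s_max=4),
        )
        acts = {
            s.indices: optimal_action_sq(X, pred.fitted, w, s) for s in subsets
        }
        fam = family_no_cv(cands, acts, pred, w, eta=0.0, eps=0.10)
        full = Subset((0, 1, 2, 3))
        assert full in fam.members
        assert fam.s_min == full  # anchor is the full subset
        # brute-force membership for the 2-subset comparison
        f = X.values[:, [0, 1]] @ acts[(0, 1)].coef
        fa = X.values @ acts[(0, 1, 2, 3)].coef
        l_s = np.mean((pred.draws - f) ** 2, axis=1)
        l_a = np.mean((pred.draws - fa) ** 2, axis=1)
        p_brute = np.mean(100 * (l_s - l_a) / l_a <= 0.0)
        assert np.isclose(fam.prob_within[(0, 1)], p_brute)


class TestTrainFoldAction:
    def test_uniform_weights_reduce_to_full_data_action(self, rng):
        """With uniform IS weights the training action equals the plain
        optimal action on the training rows with the full-data fit."""
        from subsetfam.actions import optimal_action_sq
        from subsetfam.family import train_fold_action

        X, y, fit, pred = _degenerate_pipeline(rng, n=24, S=50)
        mufit = fit.beta @ X.values.T
        tr = np.arange(16)
        w = WeightScheme.uniform(24)
        s = Subset((0, 1, 2))
        uniform = np.full(fit.n_draws, 1 / fit.n_draws)
        act = train_fold_action(mufit, X, w, s, tr, uniform)
        yhat_tr = mufit.mean(axis=0)[tr]
        Xtr = X.values[np.ix_(tr, s.array)]
        ref = np.linalg.lstsq(Xtr, yhat_tr, rcond=None)[0]
        assert np.allclose(act.coef, ref, atol=1e-10)

    def test_intercept_only_is_weighted_training_mean(self, rng):
        from subsetfam.family import train_fold_action

        X, y, fit, pred = _degenerate_pipeline(rng, n=20, S=30)
        mufit = fit.beta @ X.values.T
        tr = np.arange(12)
        fw = rng.dirichlet(np.ones(fit.n_draws))
        act = train_fold_action(
            mufit, X, WeightScheme.uniform(20), Subset((0,)), tr, fw
        )
        expected = (fw @ mufit[:, tr]).mean()
        assert np.isclose(act.coef[0], expected)
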