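import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import norm

import topreg as tg
from topreg.exceptions import SingularFitError, TooFewAnchorsError
from topreg.univariate import (
    MonteCarloConfig,
    StackedDesign,
    default_beta_grid,
    predicted_log_weights,
)


def _design(N, K, seed=0, mode="inverse_distance"):
    rng = np.random.default_rng(seed)
    dist = rng.random((N, N))
    dist = (dist + dist.T) / 2
    np.fill_diagonal(dist, 0.0)
    y = rng.uniform(4, 9, N)
    anchors = np.arange(K)
    return tg.build_stacked_design(dist**2, y, anchors, mode=mode)


class TestStackedDesign:
    @pytest.mark.parametrize("N, K, expected", [(10, 3, 24), (3, 2, 3)])
    def test_row_counts(self, N, K, expected):
        assert len(_design(N, K)) == expected

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(3, 30), st.integers(2, 10))
    def test_row_count_law(self, N, K):
        if K >= N:
            K = N - 1
        if K < 2:
            return
        d = _design(N, K)
        assert len(d) == K * (N - K) + K * (K - 1) // 2

    def test_anchor_pairs_appear_once(self):
        d = _design(10, 4)
        anchor_pairs = [p for p in d.pairs if p[0] < 4 and p[1] < 4]
        assert len(anchor_pairs) == 6
        assert len({frozenset(p) for p in anchor_pairs}) == 6

    def test_too_few_anchors(self):
        rng = np.random.default_rng(0)
        with pytest.raises(TooFewAnchorsError):
            tg.build_stacked_design(rng.random((5, 5)), rng.random(5), [0])


class TestFitUnivariate:
    def test_noiseless_targets_give_zero_residuals(self):
        B = tg.random_coefficients(4, seed=1)
        sim = tg.simulate_tr_data(tg.GenerativeSpec(N=50, K=4, B_true=B, sigma=0.0, seed=1))
        m = tg.fit_univariate(StackedDesign.from_weight_matrix(sim.W_tilde, sim.D_X))
        assert m.rss == pytest.approx(0.0, abs=1e-16)
        assert m.sigma2 == pytest.approx(0.0, abs=1e-18)
        assert np.abs(m.B - B).max() < 1e-8

    def test_sigma2_recovery(self):
        B = tg.random_coefficients(4, seed=2)
        sim = tg.simulate_tr_data(tg.GenerativeSpec(N=4000, K=4, B_true=B, sigma=0.5, seed=3))
        m = tg.fit_univariate(StackedDesign.from_weight_matrix(sim.W_tilde, sim.D_X))
        assert m.sigma2 == pytest.approx(0.25, rel=0.05)

    def test_duplicate_anchor_column_is_singular(self):
        rng = np.random.default_rng(4)
        D = rng.random((30, 3))
        D[:, 1] = D[:, 2]
        W = rng.normal(size=(30, 3))
        with pytest.raises(SingularFitError):
            tg.fit_univariate(StackedDesign.from_weight_matrix(W, D))

    def test_matches_multivariate_coefficients_on_shared_design(self):
        B = tg.random_coefficients(3, seed=5)
        sim = tg.simulate_tr_data(tg.GenerativeSpec(N=120, K=3, B_true=B, sigma=0.2, seed=6))
        mu = tg.fit_univariate(StackedDesign.from_weight_matrix(sim.W_tilde, sim.D_X))
        mm = tg.fit_multivariate(sim.W_tilde, sim.D_X)
        assert np.allclose(mu.B, mm.B, atol=1e-10)


class TestEstimateBeta:
    def test_twin_responses_drive_beta_to_grid_max(self):
        # every molecule has an exact activity twin: sharper kernels are
        # strictly better, so the LOO criterion runs to the grid maximum
        y = np.repeat(np.arange(10.0), 2)
        grid = default_beta_grid((y[:, None] - y[None, :]) ** 2)
        assert tg.estimate_beta(y, grid=grid) == grid.max()

    def test_constant_responses_warn_and_return_grid_min(self):
        y = np.full(12, 5.0)
        grid = np.logspace(-2, 2, 8)
        with pytest.warns(UserWarning):
            assert tg.estimate_beta(y, grid=grid) == grid.min()

    def test_estimate_within_grid(self, landscape):
        beta = tg.estimate_beta(landscape["y"])
        grid = default_beta_grid(
            (landscape["y"][:, None] - landscape["y"][None, :]) ** 2
        )
        assert grid.min() <= beta <= grid.max()


class TestMonteCarloEstimator:
    def test_point_mass_reduction(self):
        assert tg.mc_estimate_expected_weight(0.3, 0.0, 2.0) == pytest.approx(
            np.exp(-2.0 * np.exp(0.3))
        )

    def test_beta_zero_gives_one(self):
        assert tg.mc_estimate_expected_weight(0.0, 1.0, 0.0) == 1.0

    def test_matches_quadrature(self):
        mc = tg.mc_estimate_expected_weight(0.0, 0.5, 1.0, MonteCarloConfig(R=10**6, seed=1))
        s = np.sqrt(0.5)
        q, _ = quad(lambda z: np.exp(-np.exp(z)) * norm.pdf(z, scale=s), -10 * s, 10 * s)
        assert mc == pytest.approx(q, abs=1e-3)

    def test_monotone_in_beta_and_mu(self):
        cfg = MonteCarloConfig(R=20_000, seed=3)
        betas = [0.1, 0.5, 1.0, 2.0, 5.0]
        vals = [tg.mc_estimate_expected_weight(0.0, 0.5, b, cfg) for b in betas]
        assert np.all(np.diff(vals) < 0)
        mus = [-1.0, -0.5, 0.0, 0.5, 1.0]
        vals = [tg.mc_estimate_expected_weight(m, 0.5, 1.0, cfg) for m in mus]
        assert np.all(np.diff(vals) < 0)

    def test_error_shrinks_as_sqrt_R(self):
        ses = []
        for R in (1000, 10_000, 100_000):
            draws = [
                tg.mc_estimate_expected_weight(0.0, 0.5, 1.0, MonteCarloConfig(R=R, seed=s))
                for s in range(30)
            ]
            ses.append(np.std(draws))
        slope = np.polyfit(np.log([1e3, 1e4, 1e5]), np.log(ses), 1)[0]
        assert -0.65 < slope < -0.35

    def test_large_beta_fallback_warns(self):
        with pytest.warns(UserWarning):
            v = tg.mc_estimate_expected_weight(3.0, 0.5, 10.0)
        assert 0.0 <= v <= 1.0

    def test_replicate_floor_enforced(self):
        with pytest.raises(ValueError):
            MonteCarloConfig(R=10)


class TestPredict:
    def test_query_at_anchor_recovers_its_activity(self):
        # near-noiseless landscape: self-prediction should be tight
        ds, _ = tg.simulate_landscape(
            tg.LandscapeSpec(noise_sd=0.01, cliffs_per_cluster=0, seed=21)
        )
        sim = tg.pairwise_similarity_matrix(ds).values
        dist = tg.design_distances(1.0 - sim, 2)
        y = ds.activities()
        m = tg.fit_tr(dist, y, seed=2, mode="inverse_distance")
        a = int(m.anchor_indices[0])
        pred = tg.predict(m, dist[a, m.anchor_indices])
        assert abs(pred - y[a]) < 0.05

    def test_uniform_mu_gives_mean_anchor_activity(self):
        m = tg.UnivariateTRModel(
            B=np.zeros((4, 3)),
            sigma2=0.1,
            mode="inverse_distance",
            anchor_indices=np.arange(3),
            anchor_activities=np.array([2.0, 4.0, 9.0]),
        )
        assert tg.predict(m, np.zeros(3)) == pytest.approx(5.0)

    def test_gaussian_zero_sigma_is_deterministic_kernel_regression(self):
        m = tg.UnivariateTRModel(
            B=np.vstack([np.log([0.5, 1.0, 2.0]), np.zeros((3, 3))]),
            sigma2=0.0,
            mode="gaussian_kernel",
            beta=1.3,
            anchor_indices=np.arange(3),
            anchor_activities=np.array([2.0, 4.0, 9.0]),
        )
        lw = -1.3 * np.array([0.5, 1.0, 2.0])
        w = np.exp(lw)
        expected = w @ m.anchor_activities / w.sum()
        assert tg.predict(m, np.zeros(3)) == pytest.approx(expected)

    def test_predictions_bounded_by_anchor_range(self, landscape):
        dist, y = landscape["dist"], landscape["y"]
        m = tg.fit_tr(dist, y, seed=2)
        preds = tg.predict(m, dist[:30][:, m.anchor_indices])
        ya = m.anchor_activities
        assert np.all(preds >= ya.min() - 1e-9) and np.all(preds <= ya.max() + 1e-9)

    def test_ranking_surrogate_matches_weight_order(self):
        rng = np.random.default_rng(8)
        m = tg.UnivariateTRModel(
            B=np.vstack([rng.normal(size=3), rng.normal(size=(3, 3))]),
            sigma2=0.3,
            mode="gaussian_kernel",
            beta=0.7,
            anchor_indices=np.arange(3),
            anchor_activities=np.array([2.0, 4.0, 9.0]),
        )
        d = rng.random(3)
        lw = predicted_log_weights(m, d)[0]
        x = np.concatenate([[1.0], d])
        mu = x @ m.B
        cfg = MonteCarloConfig(R=100_000, seed=0)
        w = [tg.mc_estimate_expected_weight(mu[j], 0.3, 0.7, cfg) for j in range(3)]
        assert list(np.argsort(lw)) == list(np.argsort(w))


class TestPredictionInterval:
    def test_level_nesting(self):
        B = tg.random_coefficients(3, seed=9)
        sim = tg.simulate_tr_data(tg.GenerativeSpec(N=200, K=3, B_true=B, sigma=0.4, seed=9))
        m = tg.fit_univariate(StackedDesign.from_weight_matrix(sim.W_tilde, sim.D_X))
        rows = sim.D_X[:10]
        cols = np.zeros(10, dtype=int)
        lo90, hi90 = tg.prediction_interval(m, rows, cols, level=0.90)
        lo99, hi99 = tg.prediction_interval(m, rows, cols, level=0.99)
        assert np.all(lo99 < lo90) and np.all(hi99 > hi90)
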