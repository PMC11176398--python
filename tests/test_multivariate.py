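import numpy as np
import pytest
from scipy import stats

import topreg as tg
from topreg.exceptions import SingularFitError
from topreg.multivariate import make_partition


def _noiseless(N=60, K=3, seed=0):
    B = tg.random_coefficients(K, seed=seed)
    sim = tg.simulate_tr_data(tg.GenerativeSpec(N=N, K=K, B_true=B, sigma=0.0, seed=seed))
    return B, sim


class TestExtractWeights:
    @pytest.mark.parametrize(
        "ya, yn, eps, expected",
        [
            (2.0, 1.0, 0.0, 0.0),  # unit response distance
            (3.0, 1.0, 0.0, -np.log(4.0)),
            (1.5, 1.5, 1e-6, np.log(1e6)),  # tie guarded by eps
        ],
    )
    def test_entries(self, ya, yn, eps, expected):
        W = tg.extract_weights_inverse_distance(np.array([yn]), np.array([ya]), eps=eps)
        assert W[0, 0] == pytest.approx(expected)


class TestFitMultivariate:
    def test_noiseless_recovery(self):
        B, sim = _noiseless()
        m = tg.fit_multivariate(sim.W_tilde, sim.D_X)
        assert np.abs(m.B - B).max() < 1e-8
        assert np.abs(m.Sigma).max() < 1e-16

    def test_error_shrinks_with_sample_size(self):
        B = tg.random_coefficients(5, seed=11)

        def mean_err(N, seeds):
            errs = []
            for s in seeds:
                sim = tg.simulate_tr_data(
                    tg.GenerativeSpec(N=N, K=5, B_true=B, sigma=0.1, seed=s)
                )
                errs.append(np.abs(tg.fit_multivariate(sim.W_tilde, sim.D_X).B - B).max())
            return np.mean(errs)

        e1 = mean_err(500, range(5))
        e2 = mean_err(2000, range(10, 15))
        assert 0.3 < e2 / e1 < 0.7  # ~N^(-1/2) scaling

    def test_single_column_matches_simple_regression(self):
        rng = np.random.default_rng(3)
        D = rng.random((40, 1))
        W = 0.7 - 2.0 * D + rng.normal(0, 0.1, (40, 1))
        m = tg.fit_multivariate(W, D)
        lr = stats.linregress(D[:, 0], W[:, 0])
        assert m.B[0, 0] == pytest.approx(lr.intercept)
        assert m.B[1, 0] == pytest.approx(lr.slope)

    def test_duplicate_anchor_column_raises_named_error(self):
        rng = np.random.default_rng(5)
        D = rng.random((30, 3))
        D[:, 2] = D[:, 0]
        W = rng.normal(size=(30, 3))
        with pytest.raises(SingularFitError) as exc:
            tg.fit_multivariate(W, D)
        assert exc.value.anchors  # offending anchors named


class TestLognormalCorrection:
    @pytest.mark.parametrize(
        "mu, s2, expected",
        [(0.0, 0.0, 1.0), (0.0, 2.0, np.e), (1.0, 0.0, np.e)],
    )
    def test_values(self, mu, s2, expected):
        assert tg.lognormal_mean_correction(mu, s2) == pytest.approx(expected)

    def test_monte_carlo_agreement(self):
        rng = np.random.default_rng(0)
        z = rng.normal(0.0, np.sqrt(2.0), 10**7)
        assert tg.lognormal_mean_correction(0.0, 2.0) == pytest.approx(
            np.exp(z).mean(), abs=5e-3
        )


class TestPredictWeights:
    def _model(self, B, Sigma):
        k = B.shape[1]
        return tg.MultivariateTRModel(
            B=B,
            Sigma=Sigma,
            anchor_activities=np.zeros(k),
            gram_inv=np.eye(k + 1),
            n_obs=100,
        )

    def test_zero_sigma_is_plain_exponential(self):
        B, sim = _noiseless()
        m = tg.fit_multivariate(sim.W_tilde, sim.D_X)
        wp = tg.predict_weights(m, sim.D_X[0])
        x = np.concatenate([[1.0], sim.D_X[0]])
        assert np.allclose(wp.mean_weights, np.exp(x @ m.B))
        assert np.abs(wp.covariance).max() < 1e-12

    def test_scalar_lognormal_variance(self):
        m = self._model(B=np.zeros((2, 1)), Sigma=np.array([[2.0]]))
        wp = tg.predict_weights(m, np.array([0.0]))
        assert wp.mean_weights[0] == pytest.approx(np.e)
        assert wp.covariance[0, 0] == pytest.approx(np.e**2 * (np.e**2 - 1.0))

    def test_weights_strictly_positive(self, landscape):
        y = landscape["y"]
        m = tg.fit_tr_star(landscape["dist"], y, seed=1)
        wp = tg.predict_weights(m, landscape["dist"][0, list(m.partition.anchor_indices)])
        assert np.all(wp.mean_weights > 0)

    def test_noiseless_self_consistency(self):
        B, sim = _noiseless()
        m = tg.fit_multivariate(sim.W_tilde, sim.D_X)
        X = np.column_stack([np.ones(len(sim.D_X)), sim.D_X])
        assert np.allclose(X @ m.B, sim.W_tilde, atol=1e-8)

    def test_weight_distance_sensitivity_sign(self):
        B, sim = _noiseless(N=80, K=3, seed=4)
        m = tg.fit_multivariate(sim.W_tilde, sim.D_X)
        d = sim.D_X[0].copy()
        for j in range(3):
            base = tg.predict_weights(m, d).mean_weights[j]
            bumped = d.copy()
            bumped[j] += 1e-6
            diff = tg.predict_weights(m, bumped).mean_weights[j] - base
            assert np.sign(diff) == np.sign(m.B[1 + j, j])


class TestBootstrapInterval:
    def test_degenerate_interval_without_noise(self):
        B, sim = _noiseless()
        m = tg.fit_multivariate(sim.W_tilde, sim.D_X)
        lo, hi = tg.bootstrap_prediction_interval(
            m, sim.D_X[0], reps=200, seed=0, sample_coefficients=False
        )
        w = tg.predict_weights(m, sim.D_X[0]).mean_weights
        assert np.allclose(lo, hi, rtol=1e-6)
        assert np.allclose(lo, np.exp(np.log(w)), rtol=1e-6)

    def test_quantile_nesting(self):
        B = tg.random_coefficients(3, seed=2)
        sim = tg.simulate_tr_data(tg.GenerativeSpec(N=200, K=3, B_true=B, sigma=0.3, seed=5))
        m = tg.fit_multivariate(sim.W_tilde, sim.D_X)
        lo90, hi90 = tg.bootstrap_prediction_interval(m, sim.D_X[0], level=0.90, reps=2000, seed=1)
        lo99, hi99 = tg.bootstrap_prediction_interval(m, sim.D_X[0], level=0.99, reps=2000, seed=1)
        assert np.all(lo99 <= lo90) and np.all(hi99 >= hi90)

    def test_nominal_coverage_on_simulated_truth(self):
        B = tg.random_coefficients(3, seed=2)
        train = tg.simulate_tr_data(tg.GenerativeSpec(N=300, K=3, B_true=B, sigma=0.4, seed=9))
        test = tg.simulate_tr_data(tg.GenerativeSpec(N=300, K=3, B_true=B, sigma=0.4, seed=10))
        m = tg.fit_multivariate(train.W_tilde, train.D_X)
        inside = total = 0
        for i in range(300):
            lo, hi = tg.bootstrap_prediction_interval(m, test.D_X[i], reps=600, seed=100 + i)
            w_true = np.exp(test.W_tilde[i])
            inside += int(((w_true >= lo) & (w_true <= hi)).sum())
            total += 3
        assert 0.93 <= inside / total <= 0.97


class TestPredictResponse:
    def test_uniform_weights_give_mean(self):
        y = np.array([2.0, 4.0, 9.0])
        assert tg.predict_response(np.ones(3), y) == pytest.approx(y.mean())

    def test_dominant_weight_gives_that_anchor(self):
        w = np.array([1e6, 1.0])
        y = np.array([7.3, 2.0])
        assert tg.predict_response(w, y) == pytest.approx(7.3, abs=1e-4)

    def test_weighted_mean_example(self):
        assert tg.predict_response(np.array([1.0, 3.0]), np.array([2.0, 6.0])) == 5.0

    def test_prediction_inside_anchor_range(self, landscape):
        y = landscape["y"]
        m = tg.fit_tr_star(landscape["dist"], y, seed=3)
        anchors = list(m.partition.anchor_indices)
        preds = tg.predict_tr_star(m, landscape["dist"][:20, anchors])
        assert np.all(preds >= y[anchors].min() - 1e-9)
        assert np.all(preds <= y[anchors].max() + 1e-9)


class TestPartition:
    def test_disjoint_and_sized(self):
        p = make_partition(100, anchor_fraction=0.2, seed=0)
        assert not set(p.anchor_indices) & set(p.neighborhood_indices)
        assert p.n_anchors == 20
        assert len(p.neighborhood_indices) == 80

    def test_serialization_round_trip(self, tmp_path, landscape):
        m = tg.fit_tr_star(landscape["dist"], landscape["y"], seed=3)
        path = tmp_path / "m.json"
        tg.save_model(m, path)
        loaded = tg.load_model(path)
        anchors = list(m.partition.anchor_indices)
        d = landscape["dist"][:5, anchors]
        assert np.array_equal(tg.predict_tr_star(m, d), tg.predict_tr_star(loaded, d))
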