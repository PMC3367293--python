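import warnings

import numpy as np
import pytest

from morankrig import (
    KrigingConfig,
    ValidationError,
    VariogramModel,
    back_transform,
    error_metrics,
    loo_cross_validate,
    ok_weights,
    predict_grid,
    predict_point,
)
from _oracles import ok_system_solve
from conftest import make_samples

MODEL = VariogramModel("exponential", 0.1, [(0.4, 8.0)])


class TestOkWeights:
    def test_single_neighbor(self):
        lam, mu, var = ok_weights((5.0, 5.0), [(0.0, 0.0)], MODEL)
        assert lam[0] == pytest.approx(1.0)

    def test_square_symmetry(self):
        corners = [(0, 0), (2, 0), (0, 2), (2, 2)]
        lam, mu, var = ok_weights((1.0, 1.0), corners, MODEL)
        np.testing.assert_allclose(lam, 0.25, atol=1e-10)

    def test_weights_sum_to_one(self, rng):
        for _ in range(5):
            nb = rng.uniform(0, 20, size=(8, 2))
            lam, mu, var = ok_weights(rng.uniform(0, 20, size=2), nb, MODEL)
            assert lam.sum() == pytest.approx(1.0, abs=1e-8)

    def test_matches_dense_system_oracle(self, rng):
        nb = rng.uniform(0, 20, size=(8, 2))
        target = rng.uniform(0, 20, size=2)
        lam, mu, var = ok_weights(target, nb, MODEL)
        lam_o, mu_o, var_o = ok_system_solve(target, nb, lambda h: MODEL.gamma(h))
        np.testing.assert_allclose(lam, lam_o, atol=1e-8)
        assert mu == pytest.approx(mu_o, abs=1e-8)
        assert var == pytest.approx(var_o, abs=1e-8)

    def test_coincident_neighbors_singular(self):
        with pytest.raises(Exception, match="singular|Singular"):
            ok_weights((1.0, 1.0), [(0.0, 0.0), (0.0, 0.0), (2.0, 2.0)], MODEL)


class TestPredictPoint:
    def test_exact_interpolation_at_sample(self, rng):
        coords = rng.uniform(0, 20, size=(15, 2))
        vals = rng.lognormal(1.0, 0.3, size=15)
        s = make_samples(coords, vals)
        cfg = KrigingConfig(n_neighbors=8, min_neighbors=3)
        pred, var, mu = predict_point(coords[4], s, vals, MODEL, cfg)
        assert pred == pytest.approx(vals[4], abs=1e-10)

    def test_constant_field(self, rng):
        coords = rng.uniform(0, 20, size=(10, 2))
        s = make_samples(coords, np.full(10, 3.3))
        pred, var, mu = predict_point((5.0, 5.0), s, np.full(10, 3.3), MODEL,
                                      KrigingConfig(n_neighbors=6, min_neighbors=3))
        assert pred == pytest.approx(3.3, abs=1e-9)

    def test_composition_equals_weight_dot_product(self, rng):
        coords = rng.uniform(0, 20, size=(12, 2))
        vals = rng.normal(5.0, 1.0, size=12)
        s = make_samples(coords, np.abs(vals) + 1)
        cfg = KrigingConfig(n_neighbors=6, min_neighbors=3)
        target = (7.0, 9.0)
        pred, var, mu = predict_point(target, s, vals, MODEL, cfg)
        d = np.linalg.norm(coords - np.asarray(target), axis=1)
        nb = np.argsort(d, kind="stable")[:6]
        lam, mu_o, var_o = ok_weights(target, coords[nb], MODEL)
        assert pred == pytest.approx(float(lam @ vals[nb]), abs=1e-10)

    def test_variance_smaller_at_sample_than_far_away(self, rng):
        coords = rng.uniform(0, 20, size=(12, 2))
        vals = rng.normal(size=12)
        s = make_samples(coords, np.abs(vals) + 1)
        cfg = KrigingConfig(n_neighbors=6, min_neighbors=3)
        _, var_at, _ = predict_point(coords[0], s, vals, MODEL, cfg)
        _, var_far, _ = predict_point((500.0, 500.0), s, vals, MODEL, cfg)
        assert var_at < var_far


class TestBackTransform:
    def test_identity(self):
        assert back_transform(3.2, mode="none") == 3.2

    def test_naive_exp(self):
        assert back_transform(0.0, mode="naive_exp") == pytest.approx(1.0)

    def test_bias_corrected_requires_variance(self):
        with pytest.raises(ValidationError):
            back_transform(1.0, mode="bias_corrected")

    def test_bias_correction_reduces_mean_bias(self):
        # iid lognormal field: kriging the log values then back-transforming
        # naively underestimates the mean; the corrected transform does not
        rng = np.random.default_rng(21)
        biases_naive, biases_corr = [], []
        model = VariogramModel("exponential", 0.5, [(0.01, 5.0)])  # near-pure nugget
        for _ in range(50):
            coords = rng.uniform(0, 20, size=(40, 2))
            logv = rng.normal(2.0, np.sqrt(0.5), size=40)
            s = make_samples(coords, np.exp(logv))
            cfg = KrigingConfig(n_neighbors=8, min_neighbors=3)
            rep_n = loo_cross_validate(s, logv, model,
                                       KrigingConfig(n_neighbors=8, min_neighbors=3,
                                                     back_transform="naive_exp"))
            rep_c = loo_cross_validate(s, logv, model, cfg)  # bias_corrected default
            truth = np.exp(logv).mean()
            biases_naive.append(rep_n.predicted.mean() - truth)
            biases_corr.append(rep_c.predicted.mean() - truth)
        assert abs(np.mean(biases_corr)) < abs(np.mean(biases_naive))


class TestPredictGrid:
    def test_grid_at_sample_reproduces_value(self, rng):
        coords = rng.uniform(0, 10, size=(10, 2))
        vals = rng.normal(2.0, 0.5, size=10)
        s = make_samples(coords, np.abs(vals) + 1)
        cfg = KrigingConfig(n_neighbors=6, min_neighbors=3, back_transform="none")
        g = predict_grid(s, vals, MODEL, cfg, origin=tuple(coords[3]), cell_size=1.0,
                         shape=(1, 1))
        assert g.value[0, 0] == pytest.approx(vals[3], abs=1e-9)

    def test_deterministic(self, rng):
        coords = rng.uniform(0, 10, size=(12, 2))
        vals = rng.normal(size=12)
        s = make_samples(coords, np.abs(vals) + 1)
        cfg = KrigingConfig(n_neighbors=6, min_neighbors=3, back_transform="none")
        g1 = predict_grid(s, vals, MODEL, cfg, origin=(0, 0), cell_size=2.5, shape=(5, 5))
        g2 = predict_grid(s, vals, MODEL, cfg, origin=(0, 0), cell_size=2.5, shape=(5, 5))
        np.testing.assert_array_equal(g1.value, g2.value)
        np.testing.assert_array_equal(g1.variance, g2.variance)

    def test_ascii_grid_roundtrip(self, tmp_path, rng):
        coords = rng.uniform(0, 10, size=(10, 2))
        vals = rng.normal(size=10)
        s = make_samples(coords, np.abs(vals) + 1)
        cfg = KrigingConfig(n_neighbors=5, min_neighbors=3, back_transform="none")
        g = predict_grid(s, vals, MODEL, cfg, origin=(0, 0), cell_size=5.0, shape=(3, 3))
        p = tmp_path / "pred.asc"
        g.to_ascii_grid(p)
        lines = p.read_text().splitlines()
        assert lines[0].split() == ["ncols", "3"]
        assert len(lines) == 6 + 3


class TestErrorMetrics:
    def test_arithmetic_on_fixed_residuals(self):
        m = error_metrics([0.0, 0.0], [3.0, -1.0])
        assert m.ME == pytest.approx(1.0)
        assert m.MAE == pytest.approx(2.0)
        assert m.MSE == pytest.approx(5.0)
        assert m.RMSE == pytest.approx(np.sqrt(5.0))

    def test_perfect_prediction(self):
        m = error_metrics([1.0, 2.0], [1.0, 2.0], kriging_sd=[1.0, 1.0])
        assert m.ME == m.MAE == m.RMSE == m.MSE == 0.0
        assert m.RMSSE == 0.0

    def test_symmetric_residuals(self):
        m = error_metrics([0.0, 0.0], [1.0, -1.0])
        assert m.ME == 0.0 and m.MAE == 1.0 and m.RMSE == 1.0 and m.MSE == 1.0

    def test_rmse_squared_is_mse(self, rng):
        obs = rng.normal(size=100)
        pred = obs + rng.normal(size=100)
        m = error_metrics(obs, pred)
        assert m.RMSE**2 == pytest.approx(m.MSE, rel=1e-9)
        assert m.MAE <= m.RMSE

    def test_matches_formula_recomputation(self, rng):
        obs = rng.normal(10, 2, size=100)
        pred = obs + rng.normal(0, 1, size=100)
        sd = np.abs(rng.normal(1, 0.1, size=100)) + 0.1
        m = error_metrics(obs, pred, sd)
        e = pred - obs
        assert m.ME == pytest.approx(e.mean())
        assert m.MAE == pytest.approx(np.abs(e).mean())
        assert m.RMSE == pytest.approx(np.sqrt((e**2).mean()))
        assert m.RMSSE == pytest.approx(np.sqrt(((e / sd) ** 2).mean()))

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            error_metrics([1.0], [1.0, 2.0])

    def test_zero_sd_rejected(self):
        with pytest.raises(ValidationError):
            error_metrics([1.0, 2.0], [1.0, 2.0], kriging_sd=[1.0, 0.0])


class TestLooCrossValidation:
    def test_metrics_equal_per_sample_loop(self, rng):
        coords = rng.uniform(0, 30, size=(25, 2))
        logv = rng.normal(2.0, 0.5, size=25)
        s = make_samples(coords, np.exp(logv))
        cfg = KrigingConfig(n_neighbors=8, min_neighbors=3)
        rep = loo_cross_validate(s, logv, MODEL, cfg)
        # independent loop over per-sample predictions
        preds = []
        for i in range(25):
            p, v, mu = predict_point(coords[i], s, logv, MODEL, cfg, exclude=i)
            preds.append(np.exp(p + v / 2 - mu))
        np.testing.assert_allclose(rep.predicted, preds, rtol=1e-12)
        assert rep.metrics.MAE == pytest.approx(
            np.mean(np.abs(np.asarray(preds) - np.exp(logv)))
        )

    def test_smoothing_effect(self):
        # LOO predictions are less dispersed than observations in >=90% of
        # replicates: the well-known compression of kriged surfaces
        rng = np.random.default_rng(9)
        model = VariogramModel("exponential", 0.3, [(0.2, 10.0)])
        hits_sd = 0
        reps = 50
        for _ in range(reps):
            coords = rng.uniform(0, 30, size=(50, 2))
            logv = rng.normal(2.0, np.sqrt(0.5), size=50)
            s = make_samples(coords, np.exp(logv))
            rep = loo_cross_validate(
                s, logv, model,
                KrigingConfig(n_neighbors=8, min_neighbors=3, back_transform="none"),
                log_scale=False,
            )
            hits_sd += rep.predicted.std() <= rep.observed.std()
        assert hits_sd >= 0.9 * reps
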