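"""Gaussian-process training, prediction, persistence and CV."""

import numpy as np
import pytest

from csmaff.model import (
    GaussianProcessAffinityRegressor,
    GPConfig,
    cross_validate,
    load_model,
    predict,
    save_model,
    train,
)
from csmaff.signatures import SignatureVector


def make_sigs(X, schema=None, config_hash="cfg0"):
    schema = schema or tuple(f"f{i}" for i in range(X.shape[1]))
    return [
        SignatureVector(values=row.astype(float), schema=schema, config_hash=config_hash)
        for row in X
    ]


@pytest.fixture
def linear_problem():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(20, 3))
    w = np.array([1.0, -2.0, 0.5])
    y = X @ w + 4.0 + rng.normal(scale=0.01, size=20)
    return X, y


class TestRegressor:
    def test_recovers_linear_function_at_training_points(self, linear_problem):
        X, y = linear_problem
        reg = GaussianProcessAffinityRegressor(noise_init=0.01).fit(X, y)
        pred = reg.predict(X)
        assert np.abs(pred - y).max() < 0.05

    def test_posterior_mean_matches_closed_form(self, linear_problem):
        """Independent linear-algebra route through the fitted kernel."""
        X, y = linear_problem
        reg = GaussianProcessAffinityRegressor(noise_init=0.01).fit(X, y)
        gp = reg.gp_
        Xs = reg.scaler_.transform(X)
        K = gp.kernel_(Xs) + np.eye(len(y)) * gp.alpha
        x_star = Xs[3:4]
        k_star = gp.kernel_(x_star, Xs)
        mean_manual = k_star @ np.linalg.solve(K, y - gp._y_train_mean) + gp._y_train_mean
        assert reg.predict(X[3:4])[0] == pytest.approx(float(mean_manual[0]), abs=1e-8)

    def test_deterministic_given_seed(self, linear_problem):
        X, y = linear_problem
        p1 = GaussianProcessAffinityRegressor(random_state=1).fit(X, y).predict(X)
        p2 = GaussianProcessAffinityRegressor(random_state=1).fit(X, y).predict(X)
        assert np.abs(p1 - p2).max() <= 1e-10

    def test_constant_target_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError, match="constant"):
            GaussianProcessAffinityRegressor().fit(X, np.ones(10))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            GaussianProcessAffinityRegressor().fit(np.eye(3), [1.0, 2.0, 3.0])

    def test_far_extrapolation_reverts_to_prior(self, linear_problem):
        X, y = linear_problem
        reg = GaussianProcessAffinityRegressor(
            kernel="rbf", normalize_target=True, feature_standardize=False
        ).fit(X, y)
        far = np.full((1, 3), 1e6)
        mean, std = reg.predict(far, return_std=True)
        assert mean[0] == pytest.approx(y.mean(), rel=0.05)

    def test_standardization_roundtrip_identity(self, linear_problem):
        X, y = linear_problem
        reg = GaussianProcessAffinityRegressor().fit(X, y)
        back = reg.scaler_.inverse_transform(reg.scaler_.transform(X))
        assert np.abs(back - X).max() <= 1e-12


class TestTrainPredict:
    def test_train_and_predict_interpolates(self, linear_problem):
        X, y = linear_problem
        sigs = make_sigs(X)
        model = train(sigs, y, GPConfig(noise_init=0.01))
        mean, std = predict(model, sigs[0])
        assert mean == pytest.approx(y[0], abs=0.05)
        assert std >= 0

    def test_schema_mismatch_between_vectors_is_error(self, linear_problem):
        X, y = linear_problem
        sigs = make_sigs(X)
        other = make_sigs(X, schema=tuple(f"g{i}" for i in range(3)))
        with pytest.raises(ValueError, match="schema mismatch"):
            train(sigs[:10] + other[10:], y)

    def test_predict_rejects_foreign_schema(self, linear_problem):
        X, y = linear_problem
        model = train(make_sigs(X), y)
        foreign = make_sigs(X[:1], schema=("a", "b", "c"))[0]
        with pytest.raises(ValueError, match="schema"):
            predict(model, foreign)


class TestPersistence:
    def test_round_trip_predicts_identically(self, linear_problem, tmp_path):
        X, y = linear_problem
        sigs = make_sigs(X)
        model = train(sigs, y)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        for s in sigs[:5]:
            assert predict(loaded, s)[0] == pytest.approx(
                predict(model, s)[0], abs=1e-12
            )

    def test_altered_schema_hash_refused(self, linear_problem, tmp_path):
        import joblib

        X, y = linear_problem
        model = train(make_sigs(X), y)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        payload = joblib.load(path)
        payload["model"].schema = ("tampered",) * len(model.schema)
        joblib.dump(payload, path)
        with pytest.raises(ValueError, match="hash mismatch"):
            load_model(path)

    def test_typing_table_version_mismatch_refused(self, linear_problem, tmp_path):
        import joblib

        X, y = linear_problem
        model = train(make_sigs(X), y)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        payload = joblib.load(path)
        payload["model"].metadata["typing_table_version"] = "v999"
        payload["schema_hash"] = payload["model"].schema_hash()
        joblib.dump(payload, path)
        with pytest.raises(ValueError, match="typing table version"):
            load_model(path)


class TestCrossValidate:
    def test_leave_one_out_covers_every_point_once(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 2))
        y = X[:, 0] + rng.normal(scale=0.1, size=10)
        rep, oof = cross_validate(make_sigs(X), y, k=10, seed=0)
        assert rep.n == 10
        assert np.isfinite(oof).all()

    def test_noiseless_linear_data_near_perfect(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 3))
        y = X @ np.array([1.0, 0.5, -1.0]) + 5.0
        rep, _ = cross_validate(make_sigs(X), y, k=5, cfg=GPConfig(noise_init=0.001))
        assert rep.pearson_r >= 0.99

    def test_shuffled_labels_destroy_signal(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(100, 3))
        y = X @ np.array([1.0, 0.5, -1.0]) + rng.normal(scale=0.2, size=100)
        yp = rng.permutation(y)
        rep, oof = cross_validate(make_sigs(X), yp, k=10, seed=0)
        assert abs(rep.pearson_r) < 0.3
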