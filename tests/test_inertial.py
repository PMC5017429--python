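"""Inertial features and the k-NN classifier against brute-force oracles."""

import numpy as np
import pytest

from mcmine.contexts import ACTIVITIES
from mcmine.inertial import (
    channel_features,
    features_inertial,
    fit_knn,
    n_features,
    predict_knn,
    zero_crossing_rate,
)
from mcmine.synth import gen_inertial


def knn_oracle(X_train, y_train, x, k):
    """Exhaustive-distance oracle with the nearest-neighbour tie rule."""
    X_train = np.asarray(X_train, dtype=float)
    mean, scale = X_train.mean(0), X_train.std(0)
    scale = np.where(scale == 0, 1.0, scale)
    Xs = (X_train - mean) / scale
    xs = (np.asarray(x, dtype=float) - mean) / scale
    d = np.sqrt(((Xs - xs) ** 2).sum(axis=1))
    order = np.argsort(d, kind="stable")[:k]
    votes = {}
    for i in order:
        votes[y_train[i]] = votes.get(y_train[i], 0) + 1
    best = max(votes.values())
    for i in order:
        if votes[y_train[i]] == best:
            return y_train[i]


class TestChannelFeatures:
    def test_constant_channel(self):
        f = channel_features(np.full(150, 9.8), m=5)
        mean, zcr, mx, mn, std, q1, q2, q3, rng_ = f[:9]
        assert mean == pytest.approx(9.8)
        assert zcr == 0.0
        assert rng_ == 0.0
        assert std == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.isfinite(f))  # cepstrum log is floored

    def test_sine_zero_crossing_rate(self):
        """2 Hz unit sine over 3 s at 50 Hz: 12 sign changes / 149."""
        t = np.arange(150) / 50.0
        x = np.sin(2 * np.pi * 2 * t)
        assert zero_crossing_rate(x) == pytest.approx(12 / 149)
        f = channel_features(x, m=5)
        # sampled extrema sit within one sample step of the true peak
        assert f[2] == pytest.approx(1.0, abs=5e-3)   # max
        assert f[3] == pytest.approx(-1.0, abs=5e-3)  # min

    def test_quartiles_linear_interpolation(self):
        f = channel_features(np.arange(1.0, 151.0), m=5)
        assert f[5] == pytest.approx(38.25)
        assert f[6] == pytest.approx(75.5)
        assert f[7] == pytest.approx(112.75)

    def test_feature_vector_length(self):
        w = gen_inertial("Walking", 3.0, seed=0)
        assert features_inertial(w, m=5).shape == (n_features(5),)
        assert features_inertial(w, m=2).shape == (10 * 11,)

    def test_invalid_cepstrum_order(self, sitting_window):
        with pytest.raises(ValueError):
            features_inertial(sitting_window, m=0)


class TestRotationInvariance:
    def test_phone_rotation_leaves_features_unchanged(self):
        """Phone features use magnitude channels only, so any global
        rotation of the phone's accel and gyro triads is invisible."""
        w = gen_inertial("Walking", 3.0, seed=7)
        rng = np.random.default_rng(3)
        # random rotation from QR decomposition
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        w_rot = w.copy()
        w_rot[:, 0:3] = w[:, 0:3] @ q.T
        w_rot[:, 3:6] = w[:, 3:6] @ q.T
        f0 = features_inertial(w)
        f1 = features_inertial(w_rot)
        assert np.allclose(f0, f1, atol=1e-9)

    def test_prediction_invariant_to_phone_rotation(self, trained_inertial):
        w = gen_inertial("Running", 3.0, seed=11)
        q, _ = np.linalg.qr(np.random.default_rng(5).normal(size=(3, 3)))
        w_rot = w.copy()
        w_rot[:, 0:3] = w[:, 0:3] @ q.T
        w_rot[:, 3:6] = w[:, 3:6] @ q.T
        assert trained_inertial.predict_window(w) == \
            trained_inertial.predict_window(w_rot)


class TestKnn:
    def test_bookkeeping(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(160, 8))
        y = np.repeat(ACTIVITIES, 20)
        model = fit_knn(X, y, k=3)
        assert model.n_training == 160
        assert model.k == 3

    def test_k_zero_rejected(self):
        with pytest.raises(ValueError):
            fit_knn(np.zeros((5, 2)), ["Sitting"] * 5, k=0)

    def test_k_exceeding_rows_rejected(self):
        with pytest.raises(ValueError):
            fit_knn(np.zeros((2, 2)), ["Sitting"] * 2, k=3)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="Jogging"):
            fit_knn(np.zeros((3, 2)), ["Jogging"] * 3, k=1)

    def test_single_class_training(self):
        rng = np.random.default_rng(1)
        model = fit_knn(rng.normal(size=(5, 3)), ["Eating"] * 5, k=3)
        label, _ = predict_knn(model, rng.normal(size=3))
        assert label == "Eating"

    def test_exact_match_neighbourhood(self):
        X = np.array([[0.0, 0], [0.1, 0], [-0.1, 0], [5, 5], [6, 6]])
        y = ["Sitting", "Sitting", "Sitting", "Walking", "Walking"]
        model = fit_knn(X, y, k=3)
        assert predict_knn(model, X[0])[0] == "Sitting"

    def test_majority_vote_two_to_one(self):
        X = np.array([[0.0], [0.2], [1.0], [9.0]])
        y = ["Sitting", "Sitting", "Walking", "Walking"]
        model = fit_knn(X, y, k=3)
        label, counts = predict_knn(model, np.array([0.1]))
        assert label == "Sitting"
        assert counts == {"Sitting": 2, "Walking": 1}

    def test_three_way_tie_goes_to_nearest(self):
        X = np.array([[1.0], [-1.1], [1.2], [9.0]])
        y = ["Sitting", "Walking", "Eating", "Running"]
        model = fit_knn(X, y, k=3)
        # query at 0.9: nearest is the Sitting point
        label, counts = predict_knn(model, np.array([0.9]))
        assert set(counts.values()) == {1}
        assert label == "Sitting"

    def test_dimension_mismatch(self):
        model = fit_knn(np.zeros((3, 4)), ["Sitting"] * 3, k=1)
        with pytest.raises(ValueError):
            predict_knn(model, np.zeros(5))

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_exhaustive_oracle(self, trial):
        """Random training sets of <= 20 points, k = 3, vs brute force."""
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(3, 21))
        d = int(rng.integers(1, 5))
        X = rng.integers(-3, 4, size=(n, d)).astype(float)  # ties likely
        y = [ACTIVITIES[i] for i in rng.integers(0, 4, size=n)]
        model = fit_knn(X, y, k=3)
        for _ in range(10):
            x = rng.integers(-3, 4, size=d).astype(float)
            assert predict_knn(model, x)[0] == knn_oracle(X, y, x, 3)


def test_missing_device_imputation(trained_inertial):
    """A phone-only stream still yields a legal activity label."""
    w = gen_inertial("Running", 3.0, seed=2)
    label = trained_inertial.predict_window(w, missing_device="watch")
    assert label in ACTIVITIES
    with pytest.raises(ValueError):
        trained_inertial.predict_window(w, missing_device="tablet")
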