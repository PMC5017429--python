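"""Inertial activity recognition: window features + k-nearest-neighbour model.

Three-second, non-overlapping windows of 50 Hz accelerometer/gyroscope data
from a smartphone and a smartwatch are summarized by per-channel statistics
(mean, zero-crossing rate, max, min, standard deviation, quartiles, range)
plus the first ``m`` real-cepstrum coefficients, and classified with a
k-NN model (k = 3) on z-scored features.

The smartphone may be carried in any pocket or orientation, so its axes
are collapsed to rotation-invariant acceleration and turn-rate magnitude
channels before feature extraction; the smartwatch has a fixed wrist
placement and keeps its raw axes alongside the magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.fft import irfft, rfft

from .contexts import ACTIVITIES

#: raw channel layout of an inertial window (phone then watch, accel then gyro)
RAW_CHANNELS: tuple[str, ...] = (
    "phone_ax", "phone_ay", "phone_az", "phone_gx", "phone_gy", "phone_gz",
    "watch_ax", "watch_ay", "watch_az", "watch_gx", "watch_gy", "watch_gz",
)

DEFAULT_CEPSTRUM_ORDER = 5

_LOG_FLOOR = 1e-12


def real_cepstrum(x: np.ndarray, m: int) -> np.ndarray:
    """First ``m`` coefficients of the real cepstrum of ``x``.

    The real cepstrum is the inverse transform of the log magnitude
    spectrum; the log is floored so constant (zero-spectrum) channels do
    not produce infinities.
    """
    spectrum = np.abs(rfft(x))
    ceps = irfft(np.log(np.maximum(spectrum, _LOG_FLOOR)), n=len(x))
    return ceps[:m]


def zero_crossing_rate(x: np.ndarray) -> float:
    """Sign changes of the mean-removed signal divided by (n - 1)."""
    s = x - x.mean()
    return float(np.sum(s[:-1] * s[1:] < 0)) / (len(x) - 1)


def channel_features(x: np.ndarray, m: int) -> np.ndarray:
    """The 9 + m summary features of one channel."""
    q1, q2, q3 = np.percentile(x, [25, 50, 75])
    base = np.array([
        x.mean(),
        zero_crossing_rate(x),
        x.max(),
        x.min(),
        x.std(),
        q1, q2, q3,
        x.max() - x.min(),
    ])
    return np.concatenate([base, real_cepstrum(x, m)])


def effective_channels(window: np.ndarray) -> np.ndarray:
    """Map the 12 raw channels to the 10 feature channels.

    Phone: accel magnitude, gyro magnitude (orientation-invariant).
    Watch: 6 raw axes plus accel and gyro magnitudes.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 2 or w.shape[1] != len(RAW_CHANNELS):
        raise ValueError(f"expected (n, {len(RAW_CHANNELS)}) window, got {w.shape}")
    phone_acc = np.linalg.norm(w[:, 0:3], axis=1)
    phone_gyr = np.linalg.norm(w[:, 3:6], axis=1)
    watch_acc = np.linalg.norm(w[:, 6:9], axis=1)
    watch_gyr = np.linalg.norm(w[:, 9:12], axis=1)
    return np.column_stack([
        phone_acc, phone_gyr,
        w[:, 6], w[:, 7], w[:, 8], w[:, 9], w[:, 10], w[:, 11],
        watch_acc, watch_gyr,
    ])


def features_inertial(window: np.ndarray,
                      m: int = DEFAULT_CEPSTRUM_ORDER) -> np.ndarray:
    """Feature vector of one inertial window (10 channels x (9 + m))."""
    if m < 1:
        raise ValueError("cepstrum order m must be >= 1")
    eff = effective_channels(window)
    return np.concatenate([channel_features(eff[:, c], m)
                           for c in range(eff.shape[1])])


def n_features(m: int = DEFAULT_CEPSTRUM_ORDER) -> int:
    return 10 * (9 + m)


@dataclass
class KnnModel:
    """k-NN on z-scored features with a nearest-single-neighbour tie rule.

    The neighbour search is an explicit Euclidean scan with a stable sort,
    so equal distances resolve deterministically by training-row order —
    part of the classifier's contract, hence not delegated to a library
    whose tie behaviour is unspecified.
    """

    X: np.ndarray            # standardized training matrix
    y: np.ndarray            # labels
    k: int
    mean_: np.ndarray
    scale_: np.ndarray

    @property
    def n_training(self) -> int:
        return self.X.shape[0]


def fit_knn(X: Sequence, y: Sequence, k: int = 3) -> KnnModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if k < 1:
        raise ValueError("k must be >= 1")
    if X.shape[0] < k:
        raise ValueError(f"k={k} exceeds {X.shape[0]} training rows")
    unknown = set(y) - set(ACTIVITIES)
    if unknown:
        raise ValueError(f"unknown activity labels {sorted(unknown)}")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0  # constant features carry no distance
    Xs = (X - mean) / scale
    return KnnModel(X=Xs, y=y, k=k, mean_=mean, scale_=scale)


def predict_knn(model: KnnModel, x: np.ndarray) -> tuple[str, dict[str, int]]:
    """Majority label among the k nearest neighbours.

    On a vote tie the label of the single nearest neighbour among the tied
    labels wins (neighbours are rank-ordered by distance).
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (model.X.shape[1],):
        raise ValueError(
            f"query has {x.shape} features, model expects ({model.X.shape[1]},)")
    xs = (x - model.mean_) / model.scale_
    dist = np.sqrt(((model.X - xs) ** 2).sum(axis=1))
    idx = np.argsort(dist, kind="stable")[:model.k]
    neighbour_labels = [model.y[i] for i in idx]  # nearest first
    counts: dict[str, int] = {}
    for lab in neighbour_labels:
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    tied = {lab for lab, c in counts.items() if c == best}
    for lab in neighbour_labels:  # first tied label in rank order wins
        if lab in tied:
            return lab, counts
    raise AssertionError("unreachable")  # pragma: no cover


def predict_knn_batch(model: KnnModel, X: np.ndarray) -> list[str]:
    return [predict_knn(model, x)[0] for x in np.asarray(X, dtype=float)]


class InertialActivityRecognizer:
    """Window-in, label-out facade over feature extraction + k-NN.

    A window missing one device (phone-only or watch-only streams) has the
    absent device's features imputed with the training means.
    """

    recognizer_id = "inertial_activity"
    category = "activity"

    def __init__(self, m: int = DEFAULT_CEPSTRUM_ORDER, k: int = 3) -> None:
        self.m = m
        self.k = k
        self.model: Optional[KnnModel] = None

    def fit(self, windows: Sequence[np.ndarray], labels: Sequence[str]
            ) -> "InertialActivityRecognizer":
        X = np.array([features_inertial(w, self.m) for w in windows])
        self.model = fit_knn(X, labels, self.k)
        return self

    def fit_features(self, X: np.ndarray, y: Sequence[str]
                     ) -> "InertialActivityRecognizer":
        self.model = fit_knn(X, y, self.k)
        return self

    def predict_window(self, window: np.ndarray,
                       missing_device: Optional[str] = None) -> str:
        if self.model is None:
            raise RuntimeError("recognizer is not fitted")
        x = features_inertial(window, self.m)
        if missing_device is not None:
            x = self._impute(x, missing_device)
        return predict_knn(self.model, x)[0]

    def _impute(self, x: np.ndarray, missing_device: str) -> np.ndarray:
        # feature channels 0-1 come from the phone, 2-9 from the watch
        per = 9 + self.m
        if missing_device == "phone":
            sl = slice(0, 2 * per)
        elif missing_device == "watch":
            sl = slice(2 * per, 10 * per)
        else:
            raise ValueError(f"unknown device {missing_device!r}")
        x = x.copy()
        x[sl] = self.model.mean_[sl]
        return x
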