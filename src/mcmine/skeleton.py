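"""Skeleton-based activity recognition from depth-camera joint streams.

Frames of 20 3-D joints are windowed into 3-s, 50 %-overlapping segments.
Per configured joint pair the Euclidean inter-joint distance and the
elevation angle of the joint-joint vector against the horizontal plane are
computed per frame; their mean and standard deviation over the window form
the feature vector, classified with a decision tree.  Only the six indoor
activities are in scope — Walking and Running are rarely performed in
front of a stationary depth camera and are rejected at training time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .contexts import INDOOR_ACTIVITIES

#: Kinect-style 20-joint skeleton, in stream order.
JOINT_NAMES: tuple[str, ...] = (
    "HipCenter", "Spine", "ShoulderCenter", "Head",
    "ShoulderLeft", "ElbowLeft", "WristLeft", "HandLeft",
    "ShoulderRight", "ElbowRight", "WristRight", "HandRight",
    "HipLeft", "KneeLeft", "AnkleLeft", "FootLeft",
    "HipRight", "KneeRight", "AnkleRight", "FootRight",
)
N_JOINTS = len(JOINT_NAMES)

_J = {name: i for i, name in enumerate(JOINT_NAMES)}

#: the 19 bone edges of the skeleton hierarchy
BONE_PAIRS: tuple[tuple[int, int], ...] = tuple(
    (_J[a], _J[b]) for a, b in (
        ("HipCenter", "Spine"), ("Spine", "ShoulderCenter"),
        ("ShoulderCenter", "Head"),
        ("ShoulderCenter", "ShoulderLeft"), ("ShoulderLeft", "ElbowLeft"),
        ("ElbowLeft", "WristLeft"), ("WristLeft", "HandLeft"),
        ("ShoulderCenter", "ShoulderRight"), ("ShoulderRight", "ElbowRight"),
        ("ElbowRight", "WristRight"), ("WristRight", "HandRight"),
        ("HipCenter", "HipLeft"), ("HipLeft", "KneeLeft"),
        ("KneeLeft", "AnkleLeft"), ("AnkleLeft", "FootLeft"),
        ("HipCenter", "HipRight"), ("HipRight", "KneeRight"),
        ("KneeRight", "AnkleRight"), ("AnkleRight", "FootRight"),
    )
)

#: cross-limb pairs that capture posture better than bones alone
CROSS_PAIRS: tuple[tuple[int, int], ...] = tuple(
    (_J[a], _J[b]) for a, b in (
        ("HandLeft", "HandRight"), ("HandLeft", "Head"), ("HandRight", "Head"),
        ("FootLeft", "FootRight"), ("HandLeft", "HipCenter"),
        ("HandRight", "HipCenter"),
    )
)

DEFAULT_PAIRS: tuple[tuple[int, int], ...] = BONE_PAIRS + CROSS_PAIRS


def spatial_features(frame: np.ndarray,
                     pairs: Sequence[tuple[int, int]]) -> np.ndarray:
    """(distance, angle) per joint pair for one frame.

    ``frame`` is (n_joints, 3) with y vertical in the camera frame.  The
    angle is the elevation of the joint-joint vector above the horizontal
    (x, z) plane, in [-pi/2, pi/2]; coincident joints give (0, 0).
    """
    frame = np.asarray(frame, dtype=float)
    out = np.empty((len(pairs), 2))
    for i, (a, b) in enumerate(pairs):
        d = frame[b] - frame[a]
        dist = float(np.linalg.norm(d))
        horiz = float(np.hypot(d[0], d[2]))
        angle = 0.0 if dist == 0.0 else float(np.arctan2(d[1], horiz))
        out[i, 0] = dist
        out[i, 1] = angle
    return out


def temporal_features(frames: np.ndarray,
                      pairs: Sequence[tuple[int, int]] = DEFAULT_PAIRS
                      ) -> np.ndarray:
    """Window feature vector: per pair, mean and sigma of distance and angle.

    ``frames`` is (n_frames, n_joints, 3); sigma is the population standard
    deviation (zero for a single frame).  Layout per pair:
    [dist_mean, dist_std, angle_mean, angle_std].
    """
    frames = np.asarray(frames, dtype=float)
    if len(pairs) == 0:
        raise ValueError("pairs list must be non-empty")
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise ValueError("window must contain at least one frame")
    per_frame = np.stack([spatial_features(f, pairs) for f in frames])
    mean = per_frame.mean(axis=0)   # (n_pairs, 2)
    std = per_frame.std(axis=0)
    return np.column_stack([mean[:, 0], std[:, 0],
                            mean[:, 1], std[:, 1]]).ravel()


def window_frames(times: np.ndarray, frames: np.ndarray,
                  window_s: float = 3.0, hop_s: float = 1.5
                  ) -> list[tuple[float, np.ndarray]]:
    """Cut a frame stream into (t_start, frames) windows on a hop grid."""
    times = np.asarray(times, dtype=float)
    out = []
    t0 = times[0]
    # the stream extends one frame period past the last timestamp
    dt = float(np.median(np.diff(times))) if len(times) > 1 else 0.0
    end = times[-1] + dt
    start = t0
    while start + window_s <= end + 1e-9:
        mask = (times >= start - 1e-9) & (times < start + window_s - 1e-9)
        if mask.sum() >= 2:
            out.append((float(start), frames[mask]))
        start += hop_s
    return out


@dataclass
class TreeModel:
    clf: DecisionTreeClassifier
    classes: tuple[str, ...]


def fit_tree(X: np.ndarray, y: Sequence[str], seed: int = 0) -> TreeModel:
    y = np.asarray(y, dtype=object)
    bad = set(y) - set(INDOOR_ACTIVITIES)
    if bad:
        raise ValueError(
            f"labels {sorted(bad)} are outside the indoor activity set")
    clf = DecisionTreeClassifier(criterion="gini", min_samples_leaf=2,
                                 random_state=seed)
    clf.fit(np.asarray(X, dtype=float), y)
    return TreeModel(clf=clf, classes=tuple(clf.classes_))


def predict_tree(model: TreeModel, x: np.ndarray) -> str:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return str(model.clf.predict(x)[0])


class SkeletonActivityRecognizer:
    """Window-in, label-out facade over joint-pair features + decision tree."""

    recognizer_id = "video_activity"
    category = "activity"

    def __init__(self, pairs: Sequence[tuple[int, int]] = DEFAULT_PAIRS,
                 seed: int = 0) -> None:
        self.pairs = tuple(pairs)
        self.seed = seed
        self.model: Optional[TreeModel] = None

    def fit(self, windows: Sequence[np.ndarray], labels: Sequence[str]
            ) -> "SkeletonActivityRecognizer":
        X = np.array([temporal_features(w, self.pairs) for w in windows])
        self.model = fit_tree(X, labels, self.seed)
        return self

    def fit_features(self, X: np.ndarray, y: Sequence[str]
                     ) -> "SkeletonActivityRecognizer":
        self.model = fit_tree(X, y, self.seed)
        return self

    def predict_window(self, frames: np.ndarray) -> str:
        if self.model is None:
            raise RuntimeError("recognizer is not fitted")
        return predict_tree(self.model, temporal_features(frames, self.pairs))
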