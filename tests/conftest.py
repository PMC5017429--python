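"""Shared fixtures: small synthetic datasets and trained recognizers.

The heavier fixtures are session-scoped so feature extraction and model
training run once per test session.
"""

from __future__ import annotations

import numpy as np
import pytest

from mcmine.audio import AudioEmotionRecognizer
from mcmine.inertial import InertialActivityRecognizer
from mcmine.skeleton import SkeletonActivityRecognizer
from mcmine.synth import (
    default_personal_map,
    emotion_dataset,
    gen_inertial,
    inertial_dataset,
    skeleton_dataset,
)

SEED = 1234


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def personal_map():
    return default_personal_map("u1")


@pytest.fixture(scope="session")
def small_inertial_dataset():
    return inertial_dataset(n_subjects=4, windows_per_class=6, seed=SEED)


@pytest.fixture(scope="session")
def small_skeleton_dataset():
    return skeleton_dataset(n_subjects=4, stream_s=12.0, seed=SEED)


@pytest.fixture(scope="session")
def small_emotion_dataset():
    return emotion_dataset(n_subjects=4, segments_per_class=4, seed=SEED)


@pytest.fixture(scope="session")
def trained_inertial(small_inertial_dataset):
    windows, labels = [], []
    for ws, ys in small_inertial_dataset.values():
        windows.extend(ws)
        labels.extend(ys)
    return InertialActivityRecognizer().fit(windows, labels)


@pytest.fixture(scope="session")
def trained_skeleton(small_skeleton_dataset):
    windows, labels = [], []
    for ws, ys in small_skeleton_dataset.values():
        windows.extend(ws)
        labels.extend(ys)
    return SkeletonActivityRecognizer().fit(windows, labels)


@pytest.fixture(scope="session")
def trained_emotion(small_emotion_dataset):
    segments, labels = [], []
    for ws, ys in small_emotion_dataset.values():
        segments.extend(ws)
        labels.extend(ys)
    return AudioEmotionRecognizer().fit(segments, labels)


@pytest.fixture
def sitting_window():
    return gen_inertial("Sitting", 3.0, 50.0, seed=SEED)
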