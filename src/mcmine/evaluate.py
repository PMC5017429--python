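"""Evaluation harness: LOSO cross-validation and online scenario replay.

Per-recognizer evaluation follows a leave-one-subject-out protocol: for
each subject, models are trained on every other subject and scored on the
held-out one; per-fold confusion matrices are pooled by elementwise sum.
The holistic evaluation replays scripted multimodal scenarios through the
full pipeline and compares the predicted low- and high-level context
timelines against the script's ground truth at fusion-slot resolution,
excluding slots adjacent to context transitions (the recognizers carry no
null-class / transition model, so windows straddling a boundary are
undefined territory).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .audio import AudioEmotionRecognizer, features_audio
from .contexts import HlcDefinition, default_definitions
from .fusion import DEFAULT_SLOT_S, FusionConfig
from .geo import GeoLocationRecognizer, PersonalMap
from .inertial import InertialActivityRecognizer, features_inertial
from .pipeline import ContextPipeline, PipelineResult
from .skeleton import SkeletonActivityRecognizer, temporal_features
from .synth import GroundTruth, ScenarioScript, gen_scenario

# ---------------------------------------------------------------------------
# Confusion matrices and F-scores
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    labels: tuple[str, ...]
    counts: np.ndarray  # (n_labels, n_labels), true x predicted

    @classmethod
    def empty(cls, labels: Sequence[str]) -> "ConfusionMatrix":
        n = len(labels)
        return cls(tuple(labels), np.zeros((n, n), dtype=int))

    @classmethod
    def from_predictions(cls, y_true: Sequence[str], y_pred: Sequence[str],
                         labels: Sequence[str]) -> "ConfusionMatrix":
        cm = cls.empty(labels)
        index = {lab: i for i, lab in enumerate(labels)}
        for t, p in zip(y_true, y_pred, strict=True):
            cm.counts[index[t], index[p]] += 1
        return cm

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValueError("label sets differ")
        return ConfusionMatrix(self.labels, self.counts + other.counts)

    @property
    def support(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else 0.0

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.counts, index=list(self.labels),
                     columns=list(self.labels)).to_csv(path)


def f_score(cm: ConfusionMatrix) -> tuple[dict[str, float], float]:
    """Per-class F1 and unweighted macro mean; undefined ratios give 0."""
    per_class: dict[str, float] = {}
    for i, label in enumerate(cm.labels):
        tp = cm.counts[i, i]
        fp = cm.counts[:, i].sum() - tp
        fn = cm.counts[i, :].sum() - tp
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        per_class[label] = (2 * precision * recall / (precision + recall)
                            if precision + recall else 0.0)
    macro = float(np.mean(list(per_class.values())))
    return per_class, macro


# ---------------------------------------------------------------------------
# LOSO cross-validation
# ---------------------------------------------------------------------------

_RecognizerKinds = {
    "inertial": (InertialActivityRecognizer,
                 lambda w: features_inertial(w)),
    "skeleton": (SkeletonActivityRecognizer,
                 lambda w: temporal_features(w)),
    "emotion": (AudioEmotionRecognizer,
                lambda s: features_audio(s)),
}


@dataclass
class LosoResult:
    per_fold: dict[int, ConfusionMatrix]
    pooled: ConfusionMatrix

    @property
    def macro_f(self) -> float:
        return f_score(self.pooled)[1]


def loso_evaluate(dataset: dict[int, tuple[list, list]],
                  recognizer_kind: str) -> LosoResult:
    """Leave-one-subject-out evaluation of one recognizer kind.

    ``dataset`` maps subject -> (raw windows/segments, labels).  Features
    are extracted once per subject; every fold trains on the remaining
    subjects and tests on the held-out one.
    """
    if recognizer_kind not in _RecognizerKinds:
        raise ValueError(f"unknown recognizer kind {recognizer_kind!r}")
    if len(dataset) < 2:
        raise ValueError("LOSO needs at least two subjects")
    cls, featurize = _RecognizerKinds[recognizer_kind]
    feats = {s: (np.array([featurize(w) for w in ws]), np.asarray(ys, dtype=object))
             for s, (ws, ys) in dataset.items()}
    labels = sorted({lab for _, ys in feats.values() for lab in ys})
    for held_out in dataset:
        train_labels = {lab for s, (_, ys) in feats.items()
                        if s != held_out for lab in ys}
        missing = set(labels) - train_labels
        if missing:
            raise ValueError(
                f"classes {sorted(missing)} absent from training folds")
    per_fold: dict[int, ConfusionMatrix] = {}
    pooled = ConfusionMatrix.empty(labels)
    for held_out in sorted(dataset):
        X_tr = np.vstack([feats[s][0] for s in sorted(dataset)
                          if s != held_out])
        y_tr = np.concatenate([feats[s][1] for s in sorted(dataset)
                               if s != held_out])
        X_te, y_te = feats[held_out]
        model = cls().fit_features(X_tr, y_tr)
        if recognizer_kind == "inertial":
            from .inertial import predict_knn
            y_hat = [predict_knn(model.model, x)[0] for x in X_te]
        elif recognizer_kind == "skeleton":
            from .skeleton import predict_tree
            y_hat = [predict_tree(model.model, x) for x in X_te]
        else:
            from .audio import predict_svm
            y_hat = [predict_svm(model.model, x) for x in X_te]
        cm = ConfusionMatrix.from_predictions(y_te, y_hat, labels)
        per_fold[held_out] = cm
        pooled = pooled + cm
    return LosoResult(per_fold=per_fold, pooled=pooled)


# ---------------------------------------------------------------------------
# Online replay
# ---------------------------------------------------------------------------

#: a slot is transitional when a recognizer window contributing to it can
#: straddle a script boundary; with 3-s windows at up to 50 % overlap that
#: is any slot intersecting (boundary - 3 s, boundary + 3 s)
TRANSITION_MARGIN_S = 3.0


def timeline_label(truth_track: list[tuple[str, float, float]],
                   t: float) -> Optional[str]:
    for label, t0, t1 in truth_track:
        if t0 <= t < t1:
            return label
    return None


def predicted_timeline(events, t_slots: np.ndarray, slot_s: float,
                       label_key: str = "label") -> list[Optional[str]]:
    """Slot labels implied by a change/final event stream."""
    out: list[Optional[str]] = []
    for t in t_slots:
        current: Optional[str] = None
        for ev in events:
            ev_t = ev.t if hasattr(ev, "t") else ev.t_start
            if ev_t <= t:
                current = None if getattr(ev, "kind", "change") == "final" \
                    else getattr(ev, label_key, None)
            else:
                break
        out.append(current)
    return out


@dataclass
class TimelineComparison:
    """Aligned actual/predicted label tracks at slot resolution."""

    t_slots: np.ndarray
    actual: dict[str, list[Optional[str]]]
    predicted: dict[str, list[Optional[str]]]
    transition_mask: np.ndarray  # True = slot excluded from scoring

    def slot_accuracy(self, track: str) -> float:
        ok = total = 0
        for i, t in enumerate(self.t_slots):
            if self.transition_mask[i]:
                continue
            a = self.actual[track][i]
            if a is None:
                continue
            total += 1
            if self.predicted[track][i] == a:
                ok += 1
        return ok / total if total else 0.0

    def track_f(self, track: str) -> float:
        pairs = [(a, p) for i, (a, p) in enumerate(
            zip(self.actual[track], self.predicted[track]))
            if not self.transition_mask[i] and a is not None and p is not None]
        if not pairs:
            return 0.0
        labels = sorted({a for a, _ in pairs} | {p for _, p in pairs})
        cm = ConfusionMatrix.from_predictions(
            [a for a, _ in pairs], [p for _, p in pairs], labels)
        return f_score(cm)[1]


def hlc_truth_track(truth: GroundTruth,
                    defs: Sequence[HlcDefinition]
                    ) -> list[tuple[str, float, float]]:
    """Ground-truth high-level class per scripted step."""
    from .contexts import HighLevelContext, LowLevelContext, classify_hlc
    track = []
    for a_label, t0, t1 in truth["activity"]:
        llcs = [LowLevelContext("gt", "activity", a_label, t0, t1)]
        loc = timeline_label(truth["location"], t0)
        if loc is not None:
            llcs.append(LowLevelContext("gt", "location", loc, t0, t1))
        emo = timeline_label(truth["emotion"], t0)
        if emo is not None:
            llcs.append(LowLevelContext("gt", "emotion", emo, t0, t1))
        hlc = HighLevelContext("gt", tuple(llcs), t0, t1)
        track.append((classify_hlc(hlc, defs), t0, t1))
    return track


def compare_timelines(result: PipelineResult, truth: GroundTruth,
                      defs: Sequence[HlcDefinition],
                      slot_s: float = DEFAULT_SLOT_S) -> TimelineComparison:
    duration = max(t1 for _, _, t1 in truth["activity"])
    t_slots = np.arange(0.0, duration, slot_s)
    boundaries = sorted({t0 for track in truth.values()
                         for _, t0, _ in track if t0 > 0})
    mask = np.zeros(len(t_slots), dtype=bool)
    for b in boundaries:
        lo, hi = b - TRANSITION_MARGIN_S, b + TRANSITION_MARGIN_S
        mask |= (t_slots < hi) & (t_slots + slot_s > lo)

    actual: dict[str, list[Optional[str]]] = {}
    predicted: dict[str, list[Optional[str]]] = {}
    hlc_truth = hlc_truth_track(truth, defs)
    for cat in ("activity", "emotion", "location"):
        actual[cat] = [timeline_label(truth[cat], t) for t in t_slots]
        events = [e for e in result.llc_events if e.category == cat]
        predicted[cat] = predicted_timeline(events, t_slots, slot_s)
    actual["hlc"] = [timeline_label(hlc_truth, t) for t in t_slots]
    predicted["hlc"] = predicted_timeline(result.hlc_events, t_slots,
                                          slot_s, label_key="hlc_class")
    return TimelineComparison(t_slots, actual, predicted, mask)


@dataclass
class ReplayResult:
    comparison: TimelineComparison
    pipeline_result: PipelineResult

    def metrics(self) -> dict:
        c = self.comparison
        return {
            "hlc_slot_accuracy": c.slot_accuracy("hlc"),
            "activity_slot_accuracy": c.slot_accuracy("activity"),
            "emotion_slot_accuracy": c.slot_accuracy("emotion"),
            "location_slot_accuracy": c.slot_accuracy("location"),
            "activity_f": c.track_f("activity"),
            "emotion_f": c.track_f("emotion"),
            "location_f": c.track_f("location"),
            "hlc_f": c.track_f("hlc"),
            "n_llc_events": len(self.pipeline_result.llc_events),
            "n_hlc_events": len(self.pipeline_result.hlc_events),
        }


def replay(script: ScenarioScript, pmap: PersonalMap,
           inertial: InertialActivityRecognizer,
           skeleton: Optional[SkeletonActivityRecognizer],
           emotion: Optional[AudioEmotionRecognizer],
           defs: Optional[Sequence[HlcDefinition]] = None,
           subject: Optional[int] = None,
           fusion_cfg: Optional[FusionConfig] = None) -> ReplayResult:
    """Generate a scenario, drive it through the pipeline, score it."""
    if defs is None:
        defs = default_definitions()
    packets, truth = gen_scenario(script, pmap, subject=subject)
    pipeline = ContextPipeline(inertial, skeleton, emotion,
                               GeoLocationRecognizer(pmap), defs, fusion_cfg)
    result = pipeline.process(packets)
    comparison = compare_timelines(result, truth, defs)
    return ReplayResult(comparison=comparison, pipeline_result=result)
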