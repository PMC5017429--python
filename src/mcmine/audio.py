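"""Audio emotion recognition from phone-call speech.

The signal is framed at 25 ms / 10 ms hop.  An energy-based voice activity
detector separates voiced frames from silence; the voiced stream is cut
into non-overlapping 3-s segments whose order is randomized (a
privacy-preserving shuffle — call content cannot be reconstructed from the
segment order).  Each segment is described by log-energy statistics, an
autocorrelation pitch estimate over voiced frames, energy functionals
(min, max, skewness) and the first 13 mel-frequency cepstral coefficients
(mean and sigma over frames).  Classification uses an RBF-kernel SVM with
gamma = 0.01 and C = 1 (one-vs-one multiclass) on z-scored features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.fft import dct, irfft, rfft
from scipy.stats import skew
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .contexts import EMOTIONS

DEFAULT_RATE = 44100
SEGMENT_S = 3.0
FRAME_S = 0.025
HOP_S = 0.010

VAD_MEDIAN_FACTOR = 1.5
PITCH_FMIN = 60.0
PITCH_FMAX = 400.0
N_MFCC = 13
N_MELS = 26
N_FFT = 2048
_EPS = 1e-12


# ---------------------------------------------------------------------------
# Framing
# ---------------------------------------------------------------------------

def frame_signal(x: np.ndarray, rate: float, frame_s: float = FRAME_S,
                 hop_s: float = HOP_S) -> np.ndarray:
    """(n_frames, frame_len) view of ``x`` on the standard frame grid."""
    x = np.asarray(x, dtype=float)
    n_frame = int(round(frame_s * rate))
    n_hop = int(round(hop_s * rate))
    if len(x) < n_frame:
        return np.empty((0, n_frame))
    n = 1 + (len(x) - n_frame) // n_hop
    view = np.lib.stride_tricks.sliding_window_view(x, n_frame)
    return view[::n_hop][:n]


def frame_energies(x: np.ndarray, rate: float) -> np.ndarray:
    frames = frame_signal(x, rate)
    return (frames ** 2).mean(axis=1)


# ---------------------------------------------------------------------------
# Voice activity detection
# ---------------------------------------------------------------------------

def vad_filter(x: np.ndarray, rate: float = DEFAULT_RATE,
               factor: float = VAD_MEDIAN_FACTOR) -> np.ndarray:
    """Boolean voiced mask per 25 ms frame (10 ms hop).

    A frame is voiced when its energy exceeds an adaptive threshold,
    ``min(factor * median, 0.5 * max)`` of the frame energies: the median
    term tracks the noise floor while the max term keeps a uniformly loud
    signal from suppressing itself.  An all-silent signal yields an
    all-false mask.
    """
    if len(np.atleast_1d(x)) == 0:
        raise ValueError("empty signal")
    e = frame_energies(x, rate)
    if e.size == 0:
        return np.zeros(0, dtype=bool)
    emax = e.max()
    if emax <= _EPS:
        return np.zeros(e.size, dtype=bool)
    threshold = min(factor * float(np.median(e)), 0.5 * float(emax))
    return e > threshold


def voiced_sample_mask(x: np.ndarray, rate: float = DEFAULT_RATE) -> np.ndarray:
    """Per-sample voiced mask: a sample is voiced if any covering frame is."""
    mask = vad_filter(x, rate)
    n_frame = int(round(FRAME_S * rate))
    n_hop = int(round(HOP_S * rate))
    out = np.zeros(len(x), dtype=bool)
    for i in np.nonzero(mask)[0]:
        out[i * n_hop:i * n_hop + n_frame] = True
    # the sub-frame tail inherits the last frame's verdict
    if mask.size and mask[-1]:
        out[(mask.size - 1) * n_hop:] = True
    return out


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

@dataclass
class AudioSegment:
    samples: np.ndarray
    rate: float
    voiced_fraction: float

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


def segment_and_shuffle(x: np.ndarray, rate: float = DEFAULT_RATE,
                        seed: int = 0) -> list[AudioSegment]:
    """Silence-trimmed, non-overlapping 3-s segments in randomized order.

    Silence is removed first (VAD), the voiced stream is cut into 3-s
    segments (a trailing partial segment is dropped) and the segment order
    is permuted with a seeded RNG so the original conversation order is
    not recoverable from the output.
    """
    x = np.asarray(x, dtype=float)
    voiced = x[voiced_sample_mask(x, rate)]
    n_seg = int(round(SEGMENT_S * rate))
    n = len(voiced) // n_seg
    if n == 0:
        return []
    segments = []
    for i in range(n):
        seg = voiced[i * n_seg:(i + 1) * n_seg]
        vf = float(np.mean(vad_filter(seg, rate)))
        segments.append(AudioSegment(seg, rate, vf))
    order = np.random.default_rng(seed).permutation(n)
    return [segments[i] for i in order]


# ---------------------------------------------------------------------------
# Pitch
# ---------------------------------------------------------------------------

def pitch_autocorr(frames: np.ndarray, rate: float,
                   fmin: float = PITCH_FMIN, fmax: float = PITCH_FMAX
                   ) -> np.ndarray:
    """Per-frame f0 (Hz) via the autocorrelation peak in [fmin, fmax].

    The autocorrelation is computed through the power spectrum; the peak
    lag is refined by parabolic interpolation.
    """
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    n = frames.shape[1]
    lag_min = max(2, int(np.floor(rate / fmax)))
    lag_max = min(n - 2, int(np.ceil(rate / fmin)))
    if lag_max <= lag_min:
        raise ValueError("frame too short for the pitch search band")
    frames = frames - frames.mean(axis=1, keepdims=True)
    spec = rfft(frames, n=2 * n, axis=1)
    r = irfft(np.abs(spec) ** 2, axis=1)[:, :n]
    band = r[:, lag_min:lag_max + 1]
    peak = np.argmax(band, axis=1) + lag_min
    # parabolic refinement around the integer peak
    rl = r[np.arange(len(peak)), peak - 1]
    rc = r[np.arange(len(peak)), peak]
    rr = r[np.arange(len(peak)), peak + 1]
    denom = rl - 2 * rc + rr
    delta = np.where(np.abs(denom) > _EPS, 0.5 * (rl - rr) / denom, 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    return rate / (peak + delta)


# ---------------------------------------------------------------------------
# MFCC
# ---------------------------------------------------------------------------

def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(rate: float, n_fft: int = N_FFT, n_mels: int = N_MELS,
                   fmin: float = 0.0, fmax: Optional[float] = None
                   ) -> np.ndarray:
    """Triangular mel filterbank, (n_mels, n_fft // 2 + 1)."""
    if fmax is None:
        fmax = rate / 2
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    bins = np.floor((n_fft + 1) * hz_pts / rate).astype(int)
    fb = np.zeros((n_mels, n_fft // 2 + 1))
    for i in range(n_mels):
        lo, mid, hi = bins[i], bins[i + 1], bins[i + 2]
        if mid > lo:
            fb[i, lo:mid] = (np.arange(lo, mid) - lo) / (mid - lo)
        if hi > mid:
            fb[i, mid:hi] = (hi - np.arange(mid, hi)) / (hi - mid)
    return fb


def mfcc_frames(frames: np.ndarray, rate: float, n_mfcc: int = N_MFCC
                ) -> np.ndarray:
    """First ``n_mfcc`` MFCCs per frame (Hamming window, DCT-II ortho).

    Coefficient 0 carries overall log energy; a pure gain change shifts
    only this coefficient.
    """
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    win = np.hamming(frames.shape[1])
    spec = np.abs(rfft(frames * win, n=N_FFT, axis=1)) ** 2
    fb = mel_filterbank(rate)
    mel_energy = np.log(spec @ fb.T + _EPS)
    return dct(mel_energy, type=2, axis=1, norm="ortho")[:, :n_mfcc]


# ---------------------------------------------------------------------------
# Segment features
# ---------------------------------------------------------------------------

#: layout of the 34-dimensional feature vector
FEATURE_NAMES: tuple[str, ...] = (
    ("logE_mean", "logE_std",
     "f0_mean", "f0_std", "f0_range",
     "energy_min", "energy_max", "energy_skew")
    + tuple(f"mfcc{i}_mean" for i in range(N_MFCC))
    + tuple(f"mfcc{i}_std" for i in range(N_MFCC))
)


def features_audio(segment: AudioSegment) -> np.ndarray:
    """Feature vector of one voiced segment; raises if no frame is voiced."""
    x = segment.samples
    rate = segment.rate
    frames = frame_signal(x, rate)
    if frames.shape[0] == 0:
        raise ValueError("segment shorter than one frame")
    e = (frames ** 2).mean(axis=1)
    voiced = vad_filter(x, rate)
    if not voiced.any():
        raise ValueError("segment contains no voiced frames")
    log_e = np.log(e + _EPS)
    f0 = pitch_autocorr(frames[voiced], rate)
    mfcc = mfcc_frames(frames, rate)
    return np.concatenate([
        [log_e.mean(), log_e.std(),
         f0.mean(), f0.std(), f0.max() - f0.min(),
         e.min(), e.max(), float(skew(e)) if len(e) > 2 else 0.0],
        mfcc.mean(axis=0),
        mfcc.std(axis=0),
    ])


# ---------------------------------------------------------------------------
# SVM model
# ---------------------------------------------------------------------------

@dataclass
class SvmModel:
    clf: SVC
    scaler: StandardScaler
    constant_label: Optional[str] = None  # degenerate single-class training

    @property
    def gamma(self):
        return self.clf.gamma

    @property
    def C(self):
        return self.clf.C


def fit_svm(X: np.ndarray, y: Sequence[str], gamma: float = 0.01,
            C: float = 1.0, grid_search: bool = False) -> SvmModel:
    y = np.asarray(y, dtype=object)
    bad = set(y) - set(EMOTIONS)
    if bad:
        raise ValueError(f"unknown emotion labels {sorted(bad)}")
    X = np.asarray(X, dtype=float)
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    if len(set(y)) == 1:
        return SvmModel(clf=SVC(kernel="rbf", gamma=gamma, C=C),
                        scaler=scaler, constant_label=str(y[0]))
    if grid_search and len(set(y)) > 1:
        from sklearn.model_selection import GridSearchCV
        grid = GridSearchCV(
            SVC(kernel="rbf", decision_function_shape="ovo"),
            {"gamma": [1e-3, 1e-2, 1e-1], "C": [0.1, 1.0, 10.0]},
            cv=3,
        ).fit(Xs, y)
        clf = grid.best_estimator_
    else:
        clf = SVC(kernel="rbf", gamma=gamma, C=C,
                  decision_function_shape="ovo").fit(Xs, y)
    return SvmModel(clf=clf, scaler=scaler)


def predict_svm(model: SvmModel, x: np.ndarray) -> str:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if model.constant_label is not None:
        model.scaler.transform(x)  # still validates dimensionality
        return model.constant_label
    return str(model.clf.predict(model.scaler.transform(x))[0])


class AudioEmotionRecognizer:
    """Segment-in, label-out facade over audio features + SVM."""

    recognizer_id = "audio_emotion"
    category = "emotion"

    def __init__(self, gamma: float = 0.01, C: float = 1.0) -> None:
        self.gamma = gamma
        self.C = C
        self.model: Optional[SvmModel] = None

    def fit(self, segments: Sequence[AudioSegment], labels: Sequence[str]
            ) -> "AudioEmotionRecognizer":
        X = np.array([features_audio(s) for s in segments])
        self.model = fit_svm(X, labels, self.gamma, self.C)
        return self

    def fit_features(self, X: np.ndarray, y: Sequence[str]
                     ) -> "AudioEmotionRecognizer":
        self.model = fit_svm(X, y, self.gamma, self.C)
        return self

    #: minimum voiced material needed before a window is classified
    min_voiced_s = 0.5

    def predict_window(self, samples: np.ndarray,
                       rate: float = DEFAULT_RATE) -> Optional[str]:
        """Label for a raw 3-s window; None when it is essentially unvoiced.

        Silence is trimmed first so live windows match the silence-free
        training segments; windows with less than ``min_voiced_s`` of
        voiced material are skipped.
        """
        if self.model is None:
            raise RuntimeError("recognizer is not fitted")
        samples = np.asarray(samples, dtype=float)
        voiced = samples[voiced_sample_mask(samples, rate)]
        if len(voiced) < self.min_voiced_s * rate:
            return None
        frac = len(voiced) / len(samples)
        return predict_svm(self.model,
                           features_audio(AudioSegment(voiced, rate, frac)))
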