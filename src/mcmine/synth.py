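"""Synthetic multimodal streams with ground-truth context scripts.

Every recognizer in the package is trainable and testable without access
to recorded sensor data: this module generates per-class signature streams
for the 8 activities (inertial + skeleton), 4 emotions (audio) and 5
locations (GPS), plus scripted multi-step scenarios that interleave all
modalities with an exact label timeline for scoring.

The signatures are parametric caricatures, not biomechanical or phonetic
models: an activity is an oscillation of given amplitude and frequency on
top of a gravity orientation, an emotion is a harmonic voice source with a
characteristic pitch and loudness distribution, a place is a Gaussian
cloud of fixes around a map centre.  Emotion signatures deliberately
overlap in pairs (Anger/Happiness loud and high-pitched, Neutral/Sadness
soft and low-pitched) so the emotion benchmark is materially harder than
the activity ones.  Each subject carries seeded offsets on the signature
parameters, so leave-one-subject-out evaluation tests genuine
generalization across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .contexts import (
    ACTIVITIES,
    EMOTIONS,
    INDOOR_ACTIVITIES,
    LOCATIONS,
    SensoryPacket,
)
from .geo import PersonalMap, build_map
from .skeleton import JOINT_NAMES, N_JOINTS

GRAVITY = 9.81
_DEG_PER_M_LAT = 1.0 / 111195.0  # metres to degrees of latitude


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


# ---------------------------------------------------------------------------
# Inertial signatures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivitySignature:
    """Parametric motion signature of one activity.

    ``amp`` is the oscillation amplitude in m/s^2 (for ``freq`` = 0 it is
    the scale of slow aperiodic body sway instead), ``freq`` the dominant
    frequency in Hz, ``duty`` an optional on/off duty cycle for burst-like
    wrist motion (eating), and the gravity vectors orient each device.
    """

    label: str
    amp: float
    freq: float
    noise: float = 0.1
    phone_gravity: tuple[float, float, float] = (0.0, 0.0, 1.0)
    watch_gravity: tuple[float, float, float] = (0.0, -1.0, 0.0)
    duty: Optional[float] = None
    duty_freq: float = 0.3
    gyro_scale: float = 0.4


DEFAULT_ACTIVITY_SIGNATURES: dict[str, ActivitySignature] = {
    s.label: s for s in (
        ActivitySignature("Sitting", amp=0.1, freq=0.0,
                          watch_gravity=(1.0, 0.0, 0.0)),
        ActivitySignature("Standing", amp=0.15, freq=0.0,
                          watch_gravity=(0.0, -1.0, 0.0)),
        ActivitySignature("LyingDown", amp=0.05, freq=0.0,
                          phone_gravity=(0.0, 1.0, 0.0),
                          watch_gravity=(0.0, 0.0, 1.0)),
        ActivitySignature("Walking", amp=2.0, freq=2.0),
        ActivitySignature("Running", amp=6.0, freq=3.0, noise=0.3),
        ActivitySignature("Eating", amp=1.5, freq=1.5, duty=0.3,
                          duty_freq=0.3, watch_gravity=(0.7, -0.7, 0.0)),
        ActivitySignature("Stretching", amp=3.0, freq=0.2,
                          watch_gravity=(0.0, 0.0, -1.0)),
        ActivitySignature("Sweeping", amp=2.5, freq=1.0,
                          watch_gravity=(0.7, 0.0, 0.7)),
    )
}


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _jitter_direction(v, rng: np.random.Generator, sigma: float = 0.08
                      ) -> tuple[float, float, float]:
    out = _unit(np.asarray(v, dtype=float) + rng.normal(0, sigma, 3))
    return (float(out[0]), float(out[1]), float(out[2]))


def subject_activity_signatures(seed: int, subject: int
                                ) -> dict[str, ActivitySignature]:
    """Per-subject signature set with seeded parameter offsets."""
    rng = _rng(seed, subject, 90)
    out = {}
    for label, sig in DEFAULT_ACTIVITY_SIGNATURES.items():
        out[label] = replace(
            sig,
            amp=sig.amp * rng.uniform(0.9, 1.1),
            freq=sig.freq * rng.uniform(0.95, 1.05) if sig.freq else 0.0,
            noise=sig.noise * rng.uniform(0.9, 1.1),
            phone_gravity=_jitter_direction(sig.phone_gravity, rng),
            watch_gravity=_jitter_direction(sig.watch_gravity, rng),
        )
    return out


def _device_channels(sig: ActivitySignature, gravity, t: np.ndarray,
                     rng: np.random.Generator, burst: Optional[np.ndarray]
                     ) -> np.ndarray:
    """Six channels (3 accel + 3 gyro) of one device."""
    n = len(t)
    g = GRAVITY * _unit(np.asarray(gravity, dtype=float))
    if sig.freq > 0:
        phase = rng.uniform(0, 2 * np.pi, 3)
        osc = sig.amp * np.sin(2 * np.pi * sig.freq * t[:, None] + phase)
        osc *= rng.uniform(0.5, 1.0, 3)  # uneven energy across axes
    else:
        # slow aperiodic sway: heavily smoothed noise scaled to amp
        raw = rng.normal(0, 1.0, (n + 50, 3))
        kernel = np.ones(51) / 51.0
        sm = np.stack([np.convolve(raw[:, i], kernel, "valid")
                       for i in range(3)], axis=1)[:n]
        sd = sm.std(axis=0)
        sd[sd == 0] = 1.0
        osc = sig.amp * sm / sd
    if burst is not None:
        osc = osc * burst[:, None]
    accel = g[None, :] + osc + rng.normal(0, sig.noise, (n, 3))
    gphase = rng.uniform(0, 2 * np.pi, 3)
    if sig.freq > 0:
        gyro = sig.gyro_scale * sig.amp * np.sin(
            2 * np.pi * sig.freq * t[:, None] + gphase)
        if burst is not None:
            gyro = gyro * burst[:, None]
    else:
        gyro = np.zeros((n, 3))
    gyro = gyro + rng.normal(0, sig.noise * 0.5, (n, 3))
    return np.column_stack([accel, gyro])


def gen_inertial(activity: str, duration: float, rate: float = 50.0,
                 seed: int = 0,
                 signature: Optional[ActivitySignature] = None) -> np.ndarray:
    """(n, 12) phone + watch accelerometer/gyroscope stream."""
    if signature is None:
        if activity not in DEFAULT_ACTIVITY_SIGNATURES:
            raise ValueError(f"unknown activity {activity!r}")
        signature = DEFAULT_ACTIVITY_SIGNATURES[activity]
    rng = _rng(seed, 1)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    burst = None
    if signature.duty is not None:
        cycle = (t * signature.duty_freq) % 1.0
        burst = (cycle < signature.duty).astype(float)
    phone = _device_channels(signature, signature.phone_gravity, t, rng, None)
    watch = _device_channels(signature, signature.watch_gravity, t, rng, burst)
    return np.column_stack([phone, watch])


# ---------------------------------------------------------------------------
# Skeleton streams
# ---------------------------------------------------------------------------

_J = {name: i for i, name in enumerate(JOINT_NAMES)}


def _base_pose(height: float = 1.0) -> np.ndarray:
    """Standing stick figure, y up, origin at hip centre (metres)."""
    h = height
    pose = np.zeros((N_JOINTS, 3))

    def put(name, x, y, z):
        pose[_J[name]] = (x * h, y * h, z * h)

    put("HipCenter", 0.0, 0.90, 0.0)
    put("Spine", 0.0, 1.10, 0.0)
    put("ShoulderCenter", 0.0, 1.40, 0.0)
    put("Head", 0.0, 1.60, 0.0)
    for side, sx in (("Left", -1.0), ("Right", 1.0)):
        put(f"Shoulder{side}", 0.20 * sx, 1.38, 0.0)
        put(f"Elbow{side}", 0.25 * sx, 1.10, 0.0)
        put(f"Wrist{side}", 0.27 * sx, 0.85, 0.0)
        put(f"Hand{side}", 0.28 * sx, 0.78, 0.0)
        put(f"Hip{side}", 0.10 * sx, 0.88, 0.0)
        put(f"Knee{side}", 0.11 * sx, 0.50, 0.0)
        put(f"Ankle{side}", 0.12 * sx, 0.08, 0.0)
        put(f"Foot{side}", 0.13 * sx, 0.02, 0.08)
    return pose


def _pose_for(activity: str, height: float) -> np.ndarray:
    pose = _base_pose(height)
    if activity == "Sitting" or activity == "Eating":
        # lower hips, knees forward
        for name in ("HipCenter", "HipLeft", "HipRight"):
            pose[_J[name], 1] -= 0.40 * height
        for name in ("Spine", "ShoulderCenter", "Head",
                     "ShoulderLeft", "ShoulderRight", "ElbowLeft",
                     "ElbowRight", "WristLeft", "WristRight",
                     "HandLeft", "HandRight"):
            pose[_J[name], 1] -= 0.40 * height
        for name in ("KneeLeft", "KneeRight"):
            pose[_J[name], 1] = 0.45 * height
            pose[_J[name], 2] = 0.30 * height
        for name in ("AnkleLeft", "AnkleRight", "FootLeft", "FootRight"):
            pose[_J[name], 2] = 0.30 * height
    elif activity == "LyingDown":
        # rotate the body to horizontal: height axis becomes z
        pose = pose[:, [0, 2, 1]].copy()
        pose[:, 1] = 0.15 * height + 0.1 * pose[:, 1]
    elif activity == "Stretching":
        for side in ("Left", "Right"):
            sx = -1.0 if side == "Left" else 1.0
            pose[_J[f"Elbow{side}"]] = (0.25 * sx * height, 1.60 * height, 0.0)
            pose[_J[f"Wrist{side}"]] = (0.25 * sx * height, 1.85 * height, 0.0)
            pose[_J[f"Hand{side}"]] = (0.25 * sx * height, 1.95 * height, 0.0)
    return pose


#: per-class oscillation: (joints, axis, amplitude m, freq Hz)
_SKELETON_MOTION: dict[str, list[tuple[tuple[str, ...], int, float, float]]] = {
    "Sitting": [],
    "Standing": [],
    "LyingDown": [],
    "Eating": [(("HandRight", "WristRight"), 1, 0.25, 0.3),
               (("HandRight", "WristRight"), 2, 0.10, 0.3)],
    "Stretching": [(("HandLeft", "WristLeft", "ElbowLeft",
                     "HandRight", "WristRight", "ElbowRight"), 1, 0.30, 0.2)],
    "Sweeping": [(("HandLeft", "WristLeft", "HandRight", "WristRight"),
                  0, 0.25, 1.0),
                 (("ShoulderCenter", "Spine"), 0, 0.05, 1.0)],
}


def gen_skeleton(activity: str, duration: float, fps: float = 30.0,
                 seed: int = 0, height: float = 1.0,
                 jitter: float = 0.008) -> tuple[np.ndarray, np.ndarray]:
    """(times, frames) skeleton stream; frames is (n, 20, 3), y vertical."""
    if activity not in INDOOR_ACTIVITIES:
        raise ValueError(
            f"{activity!r} is not observable by the skeleton recognizer")
    rng = _rng(seed, 2)
    n = int(round(duration * fps))
    t = np.arange(n) / fps
    pose = _pose_for(activity, height)
    frames = np.repeat(pose[None, :, :], n, axis=0)
    for joints, axis, amp, freq in _SKELETON_MOTION[activity]:
        phase = rng.uniform(0, 2 * np.pi)
        wave = amp * height * np.sin(2 * np.pi * freq * t + phase)
        for name in joints:
            frames[:, _J[name], axis] += wave
    frames += rng.normal(0, jitter, frames.shape)
    return t, frames


def subject_skeleton_params(seed: int, subject: int) -> dict:
    rng = _rng(seed, subject, 91)
    return {"height": float(rng.uniform(0.9, 1.1)),
            "jitter": float(rng.uniform(0.006, 0.010))}


# ---------------------------------------------------------------------------
# Audio signatures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmotionSignature:
    """Voice-source parameters of one emotion.

    ``f0_mean``/``f0_sigma`` give the per-burst pitch distribution in Hz
    (within the 80-350 Hz speaking range); ``energy``/``energy_sigma`` the
    RMS amplitude distribution.  Anger and Happiness share a loud,
    high-pitched register and Neutral and Sadness a soft, low-pitched one,
    so the pairs confuse each other by construction.
    """

    label: str
    f0_mean: float
    f0_sigma: float
    energy: float
    energy_sigma: float


DEFAULT_EMOTION_SIGNATURES: dict[str, EmotionSignature] = {
    s.label: s for s in (
        EmotionSignature("Anger", f0_mean=235.0, f0_sigma=25.0,
                         energy=0.45, energy_sigma=0.10),
        EmotionSignature("Happiness", f0_mean=200.0, f0_sigma=28.0,
                         energy=0.28, energy_sigma=0.08),
        EmotionSignature("Neutral", f0_mean=135.0, f0_sigma=14.0,
                         energy=0.16, energy_sigma=0.05),
        EmotionSignature("Sadness", f0_mean=108.0, f0_sigma=16.0,
                         energy=0.09, energy_sigma=0.03),
    )
}


def subject_emotion_signatures(seed: int, subject: int
                               ) -> dict[str, EmotionSignature]:
    rng = _rng(seed, subject, 92)
    f0_scale = rng.uniform(0.93, 1.07)   # shared voice register shift
    e_scale = rng.uniform(0.85, 1.15)
    out = {}
    for label, sig in DEFAULT_EMOTION_SIGNATURES.items():
        out[label] = replace(
            sig,
            f0_mean=float(np.clip(sig.f0_mean * f0_scale, 85.0, 345.0)),
            energy=sig.energy * e_scale,
        )
    return out


def gen_audio(emotion: str, duration: float, rate: float = 44100.0,
              seed: int = 0,
              signature: Optional[EmotionSignature] = None) -> np.ndarray:
    """Mono speech-like signal: harmonic bursts separated by silences."""
    if signature is None:
        if emotion not in DEFAULT_EMOTION_SIGNATURES:
            raise ValueError(f"unknown emotion {emotion!r}")
        signature = DEFAULT_EMOTION_SIGNATURES[emotion]
    rng = _rng(seed, 3)
    n_total = int(round(duration * rate))
    out = np.zeros(n_total)
    pos = 0
    while pos < n_total:
        burst_n = int(rng.uniform(0.8, 1.6) * rate)
        burst_n = min(burst_n, n_total - pos)
        if burst_n > int(0.05 * rate):
            f0 = float(np.clip(rng.normal(signature.f0_mean,
                                          signature.f0_sigma), 70.0, 380.0))
            amp = max(0.01, rng.normal(signature.energy,
                                       signature.energy_sigma))
            t = np.arange(burst_n) / rate
            # slow vibrato keeps the pitch track from being a delta
            f_track = f0 * (1.0 + 0.01 * np.sin(2 * np.pi *
                                                rng.uniform(3, 6) * t))
            phase = 2 * np.pi * np.cumsum(f_track) / rate
            sig = np.zeros(burst_n)
            for h in range(1, 6):
                sig += (1.0 / h) * np.sin(h * phase + rng.uniform(0, 2 * np.pi))
            # syllabic amplitude modulation
            env = 0.7 + 0.3 * np.sin(2 * np.pi * rng.uniform(2, 5) * t
                                     + rng.uniform(0, 2 * np.pi))
            sig *= env
            sig *= amp / max(np.sqrt(np.mean(sig ** 2)), 1e-9)
            # fade edges to avoid clicks
            edge = min(int(0.01 * rate), burst_n // 4)
            if edge > 0:
                ramp = np.linspace(0, 1, edge)
                sig[:edge] *= ramp
                sig[-edge:] *= ramp[::-1]
            out[pos:pos + burst_n] = sig
        pos += burst_n
        pos += int(rng.uniform(0.15, 0.5) * rate)  # silence gap
    out += rng.normal(0, 1e-4, n_total)  # sensor noise floor
    return out


# ---------------------------------------------------------------------------
# GPS streams
# ---------------------------------------------------------------------------

GPS_JITTER_SIGMA_M = 5.0


def default_personal_map(user_id: str = "u1") -> PersonalMap:
    """Five well-separated places (hundreds of metres apart)."""
    base_lat, base_lon = 37.24, 127.18
    offsets = {"Home": (0.0, 0.0), "Office": (0.004, 0.001),
               "Restaurant": (0.001, 0.004), "Gym": (-0.003, 0.003),
               "Mall": (-0.002, -0.004)}
    return build_map(user_id, [
        {"label": lab, "lat": base_lat + dlat, "lon": base_lon + dlon,
         "radius_m": 50.0}
        for lab, (dlat, dlon) in offsets.items()
    ])


def gen_gps(location_seq: Sequence[tuple[str, float]], pmap: PersonalMap,
            rate: float = 1.0, seed: int = 0,
            transition_s: float = 0.0) -> np.ndarray:
    """(n, 3) array of (t, lat, lon) fixes for a dwell sequence.

    Fixes are jittered with sigma = 5 m around each place centre; with a
    positive ``transition_s`` each dwell is followed by a linear move to
    the next place centre.
    """
    rng = _rng(seed, 4)
    centres = {p.label: (p.lat, p.lon) for p in pmap.places}
    rows = []
    t = 0.0
    dt = 1.0 / rate
    for i, (label, dwell) in enumerate(location_seq):
        if label not in centres:
            raise ValueError(f"place {label!r} not in the personal map")
        lat0, lon0 = centres[label]
        cos_lat = np.cos(np.radians(lat0))
        n = int(round(dwell * rate))
        for _ in range(n):
            dn, de = rng.normal(0, GPS_JITTER_SIGMA_M, 2)
            rows.append((t, lat0 + dn * _DEG_PER_M_LAT,
                         lon0 + de * _DEG_PER_M_LAT / cos_lat))
            t += dt
        if transition_s > 0 and i + 1 < len(location_seq):
            lat1, lon1 = centres[location_seq[i + 1][0]]
            m = int(round(transition_s * rate))
            for j in range(m):
                a = (j + 1) / (m + 1)
                rows.append((t, lat0 + a * (lat1 - lat0),
                             lon0 + a * (lon1 - lon0)))
                t += dt
    return np.array(rows)


# ---------------------------------------------------------------------------
# Scenario scripts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioStep:
    duration: float
    activity: str
    emotion: Optional[str]
    location: str

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("step duration must be positive")
        if self.activity not in ACTIVITIES:
            raise ValueError(f"unknown activity {self.activity!r}")
        if self.emotion is not None and self.emotion not in EMOTIONS:
            raise ValueError(f"unknown emotion {self.emotion!r}")
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")


@dataclass(frozen=True)
class ScenarioScript:
    user_id: str
    steps: tuple[ScenarioStep, ...]
    seed: int = 0

    @property
    def duration(self) -> float:
        return sum(s.duration for s in self.steps)


def default_scenario_script(user_id: str, seed: int = 0,
                            step_s: float = 60.0) -> ScenarioScript:
    """A run-through touching every high-level context class."""
    mk = ScenarioStep
    return ScenarioScript(user_id, (
        mk(step_s, "Sitting", "Neutral", "Office"),     # OfficeWork
        mk(step_s, "Standing", None, "Office"),         # Inactivity
        mk(step_s, "Walking", None, "Gym"),             # Exercising
        mk(step_s, "Running", None, "Gym"),             # Exercising
        mk(step_s, "Eating", "Happiness", "Restaurant"),  # HavingMeal
        mk(step_s, "Sweeping", "Anger", "Home"),        # Housework
        mk(step_s, "LyingDown", "Sadness", "Home"),     # Inactivity
        mk(step_s, "Stretching", None, "Gym"),          # Exercising
    ), seed)


GroundTruth = dict[str, list[tuple[str, float, float]]]


def gen_scenario(script: ScenarioScript, pmap: PersonalMap,
                 subject: Optional[int] = None
                 ) -> tuple[list[SensoryPacket], GroundTruth]:
    """Time-ordered multimodal packets plus the exact label timeline.

    Inertial and GPS streams run for the whole scenario; skeleton packets
    exist only during indoor (camera-observable) activities, audio packets
    only during steps with a scripted emotion.  ``subject`` switches on
    per-subject signature offsets.
    """
    seed = script.seed
    if subject is None:
        act_sigs = DEFAULT_ACTIVITY_SIGNATURES
        emo_sigs = DEFAULT_EMOTION_SIGNATURES
        skel_par = {"height": 1.0, "jitter": 0.008}
    else:
        act_sigs = subject_activity_signatures(seed, subject)
        emo_sigs = subject_emotion_signatures(seed, subject)
        skel_par = subject_skeleton_params(seed, subject)

    packets: list[SensoryPacket] = []
    truth: GroundTruth = {"activity": [], "emotion": [], "location": []}
    t0 = 0.0
    for k, step in enumerate(script.steps):
        d = step.duration
        step_seed_key = (5, k)
        # inertial: 3-s packets
        iner = gen_inertial(step.activity, d, 50.0,
                            seed=_subseed(seed, *step_seed_key, 0),
                            signature=act_sigs[step.activity])
        _chunk(packets, script.user_id, "inertial", iner, 50.0, t0, 3.0)
        # skeleton only when the camera can see the activity
        if step.activity in INDOOR_ACTIVITIES:
            _, frames = gen_skeleton(step.activity, d, 30.0,
                                     seed=_subseed(seed, *step_seed_key, 1),
                                     **skel_par)
            flat = frames.reshape(frames.shape[0], -1)
            _chunk(packets, script.user_id, "skeleton", flat, 30.0, t0, 1.5)
        # audio only while an emotion is scripted
        if step.emotion is not None:
            sig = gen_audio(step.emotion, d, 44100.0,
                            seed=_subseed(seed, *step_seed_key, 2),
                            signature=emo_sigs[step.emotion])
            _chunk(packets, script.user_id, "audio", sig[:, None],
                   44100.0, t0, 3.0)
            truth["emotion"].append((step.emotion, t0, t0 + d))
        # gps for the whole step
        fixes = gen_gps([(step.location, d)], pmap, 1.0,
                        seed=_subseed(seed, *step_seed_key, 3))
        _chunk(packets, script.user_id, "gps", fixes[:, 1:3], 1.0, t0, 3.0)
        truth["activity"].append((step.activity, t0, t0 + d))
        truth["location"].append((step.location, t0, t0 + d))
        t0 += d
    order = {"inertial": 0, "skeleton": 1, "audio": 2, "gps": 3}
    packets.sort(key=lambda p: (p.t_start, order[p.modality]))
    return packets, truth


def _subseed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([int(seed), *key]).generate_state(1)[0]
               % (2 ** 31))


def _chunk(packets: list[SensoryPacket], user_id: str, modality: str,
           samples: np.ndarray, rate: float, t0: float,
           chunk_s: float) -> None:
    n_chunk = int(round(chunk_s * rate))
    for start in range(0, samples.shape[0], n_chunk):
        block = samples[start:start + n_chunk]
        if block.shape[0] == 0:
            continue
        packets.append(SensoryPacket(
            user_id=user_id, modality=modality,
            t_start=t0 + start / rate, sampling_rate=rate, samples=block))


# ---------------------------------------------------------------------------
# Benchmark datasets (per-subject raw windows for LOSO)
# ---------------------------------------------------------------------------

def inertial_dataset(n_subjects: int = 10, windows_per_class: int = 10,
                     seed: int = 0) -> dict[int, tuple[list, list]]:
    """subject -> (3-s windows, labels) over all 8 activities."""
    out = {}
    for s in range(n_subjects):
        sigs = subject_activity_signatures(seed, s)
        windows, labels = [], []
        for a in ACTIVITIES:
            stream = gen_inertial(a, 3.0 * windows_per_class, 50.0,
                                  seed=_subseed(seed, 10, s, ACTIVITIES.index(a)),
                                  signature=sigs[a])
            for i in range(windows_per_class):
                windows.append(stream[i * 150:(i + 1) * 150])
                labels.append(a)
        out[s] = (windows, labels)
    return out


def skeleton_dataset(n_subjects: int = 10, stream_s: float = 30.0,
                     seed: int = 0) -> dict[int, tuple[list, list]]:
    """subject -> (3-s half-overlapped windows, labels), indoor classes."""
    from .skeleton import window_frames
    out = {}
    for s in range(n_subjects):
        par = subject_skeleton_params(seed, s)
        windows, labels = [], []
        for a in INDOOR_ACTIVITIES:
            times, frames = gen_skeleton(
                a, stream_s, 30.0,
                seed=_subseed(seed, 11, s, INDOOR_ACTIVITIES.index(a)), **par)
            for _, w in window_frames(times, frames):
                windows.append(w)
                labels.append(a)
        out[s] = (windows, labels)
    return out


def emotion_dataset(n_subjects: int = 10, segments_per_class: int = 8,
                    seed: int = 0) -> dict[int, tuple[list, list]]:
    """subject -> (3-s voiced AudioSegments, labels) over the 4 emotions."""
    from .audio import segment_and_shuffle
    out = {}
    for s in range(n_subjects):
        sigs = subject_emotion_signatures(seed, s)
        segments, labels = [], []
        for e in EMOTIONS:
            # generous raw duration: the VAD trims silences and quieter
            # passages before cutting, so over-generate substantially
            raw = gen_audio(e, 8.0 * segments_per_class, 44100.0,
                            seed=_subseed(seed, 12, s, EMOTIONS.index(e)),
                            signature=sigs[e])
            segs = segment_and_shuffle(raw, 44100.0,
                                       seed=_subseed(seed, 13, s))
            for seg in segs[:segments_per_class]:
                segments.append(seg)
                labels.append(e)
        out[s] = (segments, labels)
    return out
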