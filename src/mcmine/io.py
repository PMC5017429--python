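"""On-disk stream formats and the file replay reader.

Every modality has a plain-text format (CSV with a time column, WAV for
audio); a scenario directory written by the simulator can be read back
into a time-ordered packet sequence for offline replay.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .contexts import SensoryPacket
from .inertial import RAW_CHANNELS
from .skeleton import JOINT_NAMES

_PathLike = Union[str, Path]


def write_inertial_csv(path: _PathLike, samples: np.ndarray, rate: float,
                       t0: float = 0.0) -> None:
    t = t0 + np.arange(samples.shape[0]) / rate
    df = pd.DataFrame(samples, columns=list(RAW_CHANNELS))
    df.insert(0, "t", t)
    df.to_csv(path, index=False, float_format="%.6f")


def read_inertial_csv(path: _PathLike) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["t"].to_numpy(), df[list(RAW_CHANNELS)].to_numpy()


def write_skeleton_csv(path: _PathLike, times: np.ndarray,
                       frames: np.ndarray) -> None:
    cols = [f"{axis}_{name}" for name in JOINT_NAMES for axis in "xyz"]
    flat = frames.reshape(frames.shape[0], -1)
    df = pd.DataFrame(flat, columns=cols)
    df.insert(0, "t", times)
    with open(path, "w") as fh:
        fh.write("# joint order: " + ", ".join(JOINT_NAMES) + "\n")
        df.to_csv(fh, index=False, float_format="%.5f")


def read_skeleton_csv(path: _PathLike) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, comment="#")
    t = df["t"].to_numpy()
    frames = df.drop(columns="t").to_numpy().reshape(len(df), -1, 3)
    return t, frames


def write_gps_csv(path: _PathLike, fixes: np.ndarray) -> None:
    pd.DataFrame(fixes, columns=["t", "lat", "lon"]).to_csv(
        path, index=False, float_format="%.8f")


def read_gps_csv(path: _PathLike) -> np.ndarray:
    return pd.read_csv(path)[["t", "lat", "lon"]].to_numpy()


def write_wav(path: _PathLike, signal: np.ndarray, rate: int = 44100) -> None:
    """16-bit PCM mono WAV; the float signal is clipped to [-1, 1]."""
    x = np.clip(np.asarray(signal, dtype=float), -1.0, 1.0)
    wavfile.write(str(path), int(rate), (x * 32767).astype(np.int16))


def read_wav(path: _PathLike) -> tuple[np.ndarray, int]:
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    return data.astype(float), int(rate)


def write_events_jsonl(path: _PathLike, events) -> None:
    with open(path, "w") as fh:
        for ev in events:
            fh.write(json.dumps(ev.to_dict(), sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Scenario directories
# ---------------------------------------------------------------------------

def write_scenario_dir(out_dir: _PathLike, packets, truth,
                       user_id: str) -> None:
    """Persist a generated scenario as per-modality files + ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_modality: dict[str, list] = {}
    for p in packets:
        by_modality.setdefault(p.modality, []).append(p)
    if "inertial" in by_modality:
        ps = by_modality["inertial"]
        samples = np.concatenate([p.samples for p in ps])
        write_inertial_csv(out / "inertial.csv", samples,
                           ps[0].sampling_rate, ps[0].t_start)
    if "skeleton" in by_modality:
        rows, times = [], []
        for p in by_modality["skeleton"]:
            rows.append(p.samples)
            times.append(p.t_start + np.arange(p.samples.shape[0])
                         / p.sampling_rate)
        flat = np.concatenate(rows)
        write_skeleton_csv(out / "skeleton.csv", np.concatenate(times),
                           flat.reshape(flat.shape[0], -1, 3))
    if "audio" in by_modality:
        segs = [(p.t_start, p.samples[:, 0], p.sampling_rate)
                for p in by_modality["audio"]]
        # audio is stored as one WAV per contiguous run of packets
        runs, current = [], [segs[0]]
        for prev, cur in zip(segs, segs[1:]):
            if abs(prev[0] + len(prev[1]) / prev[2] - cur[0]) < 1e-6:
                current.append(cur)
            else:
                runs.append(current)
                current = [cur]
        runs.append(current)
        index = []
        for i, run in enumerate(runs):
            signal = np.concatenate([seg for _, seg, _ in run])
            write_wav(out / f"audio_{i:03d}.wav", signal, int(run[0][2]))
            index.append({"file": f"audio_{i:03d}.wav", "t_start": run[0][0],
                          "rate": run[0][2]})
        with open(out / "audio_index.json", "w") as fh:
            json.dump(index, fh, indent=2)
    if "gps" in by_modality:
        rows = []
        for p in by_modality["gps"]:
            t = p.t_start + np.arange(p.samples.shape[0]) / p.sampling_rate
            rows.append(np.column_stack([t, p.samples]))
        write_gps_csv(out / "gps.csv", np.concatenate(rows))
    with open(out / "ground_truth.json", "w") as fh:
        json.dump({"user": user_id, "tracks": truth}, fh, indent=2)


def read_scenario_dir(scenario_dir: _PathLike
                      ) -> tuple[list[SensoryPacket], dict, str]:
    """Read a scenario directory back into time-ordered packets."""
    d = Path(scenario_dir)
    with open(d / "ground_truth.json") as fh:
        gt = json.load(fh)
    user_id = gt["user"]
    truth = {cat: [(lab, float(a), float(b)) for lab, a, b in track]
             for cat, track in gt["tracks"].items()}
    packets: list[SensoryPacket] = []
    if (d / "inertial.csv").exists():
        t, samples = read_inertial_csv(d / "inertial.csv")
        _chunk_packets(packets, user_id, "inertial", samples, 50.0, t[0], 3.0)
    if (d / "skeleton.csv").exists():
        t, frames = read_skeleton_csv(d / "skeleton.csv")
        flat = frames.reshape(frames.shape[0], -1)
        _chunk_contiguous(packets, user_id, "skeleton", t, flat, 30.0, 1.5)
    if (d / "audio_index.json").exists():
        with open(d / "audio_index.json") as fh:
            for entry in json.load(fh):
                signal, rate = read_wav(d / entry["file"])
                _chunk_packets(packets, user_id, "audio", signal[:, None],
                               float(rate), float(entry["t_start"]), 3.0)
    if (d / "gps.csv").exists():
        fixes = read_gps_csv(d / "gps.csv")
        _chunk_contiguous(packets, user_id, "gps", fixes[:, 0],
                          fixes[:, 1:3], 1.0, 3.0)
    order = {"inertial": 0, "skeleton": 1, "audio": 2, "gps": 3}
    packets.sort(key=lambda p: (p.t_start, order[p.modality]))
    return packets, truth, user_id


def _chunk_packets(packets, user_id, modality, samples, rate, t0, chunk_s):
    n = int(round(chunk_s * rate))
    for start in range(0, samples.shape[0], n):
        block = samples[start:start + n]
        if block.shape[0]:
            packets.append(SensoryPacket(user_id, modality,
                                         t0 + start / rate, rate, block))


def _chunk_contiguous(packets, user_id, modality, times, samples, rate,
                      chunk_s):
    """Chunk a timestamped stream, splitting at gaps in the time base."""
    if len(times) == 0:
        return
    dt = 1.0 / rate
    run_start = 0
    for i in range(1, len(times) + 1):
        if i == len(times) or times[i] - times[i - 1] > 1.5 * dt:
            _chunk_packets(packets, user_id, modality,
                           samples[run_start:i], rate, times[run_start],
                           chunk_s)
            run_start = i
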