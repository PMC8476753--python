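"""Plain-text serialization of recordings, stroke sets, models and results.

All formats are CSV/JSON so datasets remain diffable and portable:

* recording CSV: columns ``time_s``, the six motion channels, ``pad1``,
  ``pad2``;
* manifest CSV: one row per recording (participant, stimulation, phase,
  experiment, file);
* stroke-set CSV: columns ``stroke_id``, ``phase_index`` and the six
  channels, one file per cell and direction;
* model: a JSON header (M, T, D, lambda, noise stds, n demonstrations) next
  to a CSV payload holding the weight mean (first row) and covariance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    MOTION_CHANNELS,
    PAD_CHANNELS,
    PhaseGrid,
    RawRecording,
    StrokeSet,
)
from .promp import ProMPModel, make_basis

__all__ = [
    "write_recording_csv",
    "read_recording_csv",
    "recording_filename",
    "strokeset_filename",
    "write_strokeset_csv",
    "read_strokeset_csv",
    "save_model",
    "load_model",
]


def recording_filename(q: int, s: str, o: str, p: int) -> str:
    return f"rec_q{q}_{s}_{o}_p{p}.csv"


def strokeset_filename(q: int, s: str, o: str, p: int, direction: str) -> str:
    return f"strokes_q{q}_{s}_{o}_p{p}_{direction}.csv"


def write_recording_csv(recording: RawRecording, path: str | Path) -> None:
    frame = pd.DataFrame({"time_s": recording.time})
    for i, name in enumerate(MOTION_CHANNELS):
        frame[name] = recording.motion[:, i]
    for i, name in enumerate(PAD_CHANNELS):
        frame[name] = recording.pads[:, i]
    frame.to_csv(path, index=False, float_format="%.6g")


def read_recording_csv(
    path: str | Path, metadata: dict | None = None, sampling_rate: float | None = None
) -> RawRecording:
    frame = pd.read_csv(path)
    time = frame["time_s"].to_numpy(float)
    if sampling_rate is None:
        sampling_rate = 1.0 / float(np.median(np.diff(time)))
    motion = frame[list(MOTION_CHANNELS)].to_numpy(float)
    pads = frame[list(PAD_CHANNELS)].to_numpy(float)
    return RawRecording(sampling_rate, time, motion, pads, dict(metadata or {}))


def write_strokeset_csv(strokes: StrokeSet, path: str | Path) -> None:
    n, T, D = strokes.data.shape
    frame = pd.DataFrame(
        {
            "stroke_id": np.repeat(np.arange(n), T),
            "phase_index": np.tile(np.arange(T), n),
        }
    )
    flat = strokes.data.reshape(n * T, D)
    for i, name in enumerate(MOTION_CHANNELS):
        frame[name] = flat[:, i]
    frame.to_csv(path, index=False, float_format="%.8g")


def read_strokeset_csv(
    path: str | Path, direction: str, metadata: dict | None = None
) -> StrokeSet:
    frame = pd.read_csv(path)
    n = int(frame["stroke_id"].max()) + 1
    T = int(frame["phase_index"].max()) + 1
    data = frame[list(MOTION_CHANNELS)].to_numpy(float).reshape(n, T, len(MOTION_CHANNELS))
    return StrokeSet(data, direction, PhaseGrid.uniform(T), dict(metadata or {}))


def save_model(model: ProMPModel, prefix: str | Path) -> None:
    """Write ``<prefix>.json`` (header) and ``<prefix>_weights.csv`` (payload)."""
    prefix = Path(prefix)
    header = {
        "M": model.basis.M,
        "T": model.grid.T,
        "D": model.n_channels,
        "lambda": model.lam,
        "noise_std": model.noise_std.tolist(),
        "n_demos": model.n_demos,
        "payload": prefix.name + "_weights.csv",
    }
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(header, fh, indent=2)
    payload = np.vstack([model.weight_mean[None, :], model.weight_cov])
    np.savetxt(prefix.parent / (prefix.name + "_weights.csv"), payload, delimiter=",")


def load_model(prefix: str | Path) -> ProMPModel:
    prefix = Path(prefix)
    with open(prefix.with_suffix(".json")) as fh:
        header = json.load(fh)
    payload = np.loadtxt(prefix.parent / header["payload"], delimiter=",")
    mu, cov = payload[0], payload[1:]
    grid = PhaseGrid.uniform(header["T"])
    basis, phi = make_basis(header["M"], grid)
    return ProMPModel(
        basis,
        grid,
        phi,
        mu,
        cov,
        np.asarray(header["noise_std"], float),
        header["lambda"],
        header["n_demos"],
    )
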