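"""Shared data containers for the tapping-motion analysis pipeline.

The analysis moves through a fixed chain of representations:

``RawRecording`` (continuous 2000 Hz accelerometer + touch-pad signals)
-> ``TapEvent`` (pad contacts) -> ``Stroke`` (one point-to-point movement)
-> ``StrokeSet`` (phase-normalized strokes on a shared :class:`PhaseGrid`)
-> ``TrajectoryDistribution`` (per-phase-point, per-channel Gaussian).

Six motion channels are recorded: x/y/z acceleration of the tapping hand and
of the wrist of the same arm.  Two further channels come from accelerometers
under the touch pads and are used only for segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

MOTION_CHANNELS: tuple[str, ...] = (
    "hand_x", "hand_y", "hand_z", "wrist_x", "wrist_y", "wrist_z",
)
PAD_CHANNELS: tuple[str, ...] = ("pad1", "pad2")
N_MOTION = len(MOTION_CHANNELS)

INWARD = "inward"
OUTWARD = "outward"
DIRECTIONS = (INWARD, OUTWARD)


@dataclass(frozen=True, eq=False)
class PhaseGrid:
    """Uniform movement-phase grid.

    The movement phase z rescales each stroke's time axis to [0, 1] so that
    strokes of different durations share one resolution.  ``z`` must start at
    exactly 0, end at exactly 1 and be strictly increasing.
    """

    z: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 1 or z.size < 2:
            raise ValueError("phase grid needs at least two points")
        if z[0] != 0.0 or z[-1] != 1.0:
            raise ValueError("phase grid must span [0, 1] exactly")
        if np.any(np.diff(z) <= 0):
            raise ValueError("phase grid must be strictly increasing")
        z = z.copy()
        z.flags.writeable = False
        object.__setattr__(self, "z", z)

    @classmethod
    def uniform(cls, T: int) -> "PhaseGrid":
        """T equally spaced phase points from 0 to 1 inclusive."""
        if T < 2:
            raise ValueError("T must be >= 2")
        return cls(np.linspace(0.0, 1.0, int(T)))

    @property
    def T(self) -> int:
        return self.z.size


@dataclass(eq=False)
class RawRecording:
    """One continuous multi-channel recording (the unit of data collection).

    Parameters
    ----------
    sampling_rate : float
        Samples per second; must agree with ``time`` within 1 ppm.
    time : ndarray, shape (N,)
        Sample times in seconds, strictly increasing.
    motion : ndarray, shape (N, 6)
        Acceleration channels ordered as :data:`MOTION_CHANNELS`.
    pads : ndarray, shape (N, 2)
        Touch-pad accelerometer channels (pad 1, pad 2).
    metadata : dict
        Study indices: participant ``q``, stimulation ``s``, phase ``o``,
        experiment ``p`` (keys "participant", "stimulation", "phase",
        "experiment") plus anything the caller wants to carry along.
    truth : dict or None
        Generator ground truth (contact samples, stroke directions, ...);
        absent for real data.
    """

    sampling_rate: float
    time: np.ndarray
    motion: np.ndarray
    pads: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)
    truth: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.motion = np.asarray(self.motion, dtype=float)
        self.pads = np.asarray(self.pads, dtype=float)
        n = self.time.size
        if self.motion.shape != (n, N_MOTION):
            raise ValueError(f"motion must have shape ({n}, {N_MOTION})")
        if self.pads.shape != (n, len(PAD_CHANNELS)):
            raise ValueError(f"pads must have shape ({n}, {len(PAD_CHANNELS)})")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        dt = float(np.median(np.diff(self.time)))
        if abs(dt * self.sampling_rate - 1.0) > 1e-6:
            raise ValueError("sampling_rate inconsistent with time vector")

    @property
    def n_samples(self) -> int:
        return self.time.size

    def channel(self, name: str) -> np.ndarray:
        """Return one named channel (motion or pad) as a 1-d view."""
        if name in MOTION_CHANNELS:
            return self.motion[:, MOTION_CHANNELS.index(name)]
        if name in PAD_CHANNELS:
            return self.pads[:, PAD_CHANNELS.index(name)]
        raise KeyError(f"unknown channel {name!r}")


@dataclass(frozen=True)
class TapEvent:
    """One detected pad contact."""

    sample_index: int
    pad_id: int  # 1 or 2
    time: float


@dataclass(eq=False)
class Stroke:
    """One segmented point-to-point movement (variable length).

    ``samples`` holds the six motion channels between two consecutive pad
    contacts; the source interval ``[start_index, end_index)`` refers back to
    the recording.
    """

    samples: np.ndarray
    direction: str
    start_index: int
    end_index: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != N_MOTION:
            raise ValueError(f"samples must be (L, {N_MOTION})")
        if self.samples.shape[0] < 2:
            raise ValueError("a stroke needs at least two samples")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


@dataclass(eq=False)
class StrokeSet:
    """n phase-normalized strokes on a shared grid (the unit of model fitting).

    ``data`` has shape (n, T, 6).  At least two strokes are required: a single
    trajectory carries no variance information, and the whole analysis is
    built on per-phase-point means *and* variances.
    """

    data: np.ndarray
    direction: str
    grid: PhaseGrid
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != N_MOTION:
            raise ValueError(f"data must be (n, T, {N_MOTION})")
        if self.data.shape[0] < 2:
            raise ValueError("a StrokeSet needs at least two strokes")
        if self.data.shape[1] != self.grid.T:
            raise ValueError("data length does not match the phase grid")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("StrokeSet contains non-finite values")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")

    @property
    def n_strokes(self) -> int:
        return self.data.shape[0]


@dataclass(eq=False)
class TrajectoryDistribution:
    """Independent per-phase-point, per-channel Gaussian marginals.

    This is the object divergences are computed on: ``mean`` and ``std`` are
    (T, D) arrays over the phase grid.  Standard deviations are floored at a
    small positive value on construction so the Gaussian KL divergence is
    always defined (degenerate variance occurs e.g. with duplicated strokes).
    """

    mean: np.ndarray
    std: np.ndarray
    grid: PhaseGrid

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if self.mean.shape != self.std.shape or self.mean.ndim != 2:
            raise ValueError("mean and std must be matching 2-d arrays")
        if self.mean.shape[0] != self.grid.T:
            raise ValueError("distribution length does not match the grid")
        if not (np.all(np.isfinite(self.mean)) and np.all(np.isfinite(self.std))):
            raise ValueError("non-finite distribution parameters")
        if np.any(self.std <= 0):
            raise ValueError("std must be strictly positive (apply a floor)")

    @classmethod
    def from_moments(
        cls,
        mean: np.ndarray,
        std: np.ndarray,
        grid: PhaseGrid,
        std_floor: float = 1e-8,
    ) -> "TrajectoryDistribution":
        """Build a distribution, flooring ``std`` at ``std_floor``."""
        std = np.maximum(np.asarray(std, dtype=float), std_floor)
        return cls(np.asarray(mean, dtype=float), std, grid)

    @property
    def n_channels(self) -> int:
        return self.mean.shape[1]
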