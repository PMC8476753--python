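"""Seeded synthetic tapping recordings and full study datasets.

The generator emulates the statistical structure a finger-tapping stimulation
study produces, so every downstream stage (segmentation, ProMP fitting,
divergence statistics) can be exercised without access to recorded subjects:

* repetitive point-to-point strokes whose acceleration follows a minimum-jerk
  template, with stroke-to-stroke amplitude and duration variability;
* per-channel Gaussian sensor noise;
* touch-pad channels carrying a short rectangular pulse at every contact;
* a participants x stimulations x phases x experiments study design
  (default 10 x 4 x 5 x 8 = 1,600 recordings);
* optional stimulation effects (additive mean shifts on a phase sub-interval,
  amplitude scaling) applied to selected recording phases;
* sensor-misplacement anomalies (axis swaps / sign flips).

Every recording draws from its own random substream derived from the root
seed and the cell labels, so a cell reproduces bit-identically no matter in
which order - or within which sub-design - it is generated.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .core import (
    DIRECTIONS,
    INWARD,
    MOTION_CHANNELS,
    N_MOTION,
    OUTWARD,
    PAD_CHANNELS,
    PhaseGrid,
    RawRecording,
    StrokeSet,
)

__all__ = [
    "SyntheticConfig",
    "StimulationEffect",
    "StudyDesign",
    "AnomalySpec",
    "minimum_jerk_acceleration",
    "TEMPLATE_PEAK_FACTOR",
    "segment_template",
    "generate_stroke_profile",
    "generate_recording",
    "generate_study",
    "iter_study",
    "inject_anomaly",
    "sample_strokeset",
    "DEFAULT_AMPLITUDES",
]

# Peak |a| of the unit minimum-jerk acceleration polynomial on [0, 1].
TEMPLATE_PEAK_FACTOR = 10.0 / np.sqrt(3.0)

# Per-channel acceleration amplitudes (m/s^2 per unit polynomial value):
# the tapping axis (x) dominates, vertical (z) is intermediate, the lateral
# axis is small; the wrist moves roughly half as much as the hand.
DEFAULT_AMPLITUDES = np.array([2.0, 0.5, 1.0, 1.0, 0.25, 0.5])

STIMULATIONS = ("Sham", "tACS", "tDCS", "tRNS")
PHASES = ("Erst", "Prae", "Post1", "Post2", "Post3")
POST_PHASES = ("Post1", "Post2", "Post3")


def minimum_jerk_acceleration(u):
    """Acceleration of the minimum-jerk point-to-point trajectory.

    For the unit minimum-jerk position profile x(u) = 10u^3 - 15u^4 + 6u^5 the
    acceleration is a(u) = 60u - 180u^2 + 120u^3: smooth, biphasic
    (accelerate then decelerate) and antisymmetric about u = 1/2, which is the
    qualitative shape of a tapping stroke's acceleration.
    """
    u = np.asarray(u, dtype=float)
    return 60.0 * u - 180.0 * u**2 + 120.0 * u**3


@dataclass(frozen=True)
class StimulationEffect:
    """Synthetic stand-in for a true stimulation effect on the stroke shape.

    ``mean_shift`` (per channel, additive) is applied wherever the movement
    phase of the stroke segment falls inside ``phase_support``;
    ``amplitude_scale`` multiplies the noiseless template.  ``applies_to``
    restricts the effect to a set of recording phases (e.g. the Post
    recordings); ``None`` means every phase.
    """

    mean_shift: tuple[float, ...] = (0.0,) * N_MOTION
    amplitude_scale: float = 1.0
    phase_support: tuple[float, float] = (0.0, 1.0)
    applies_to: frozenset[str] | None = None

    def __post_init__(self) -> None:
        lo, hi = self.phase_support
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("phase_support must be a sub-interval of [0, 1]")
        if len(self.mean_shift) != N_MOTION:
            raise ValueError(f"mean_shift needs {N_MOTION} entries")
        if self.applies_to is not None:
            object.__setattr__(self, "applies_to", frozenset(self.applies_to))

    @property
    def is_identity(self) -> bool:
        return all(s == 0.0 for s in self.mean_shift) and self.amplitude_scale == 1.0

    def applies(self, phase_label: str | None) -> bool:
        if self.applies_to is None:
            return True
        return phase_label in self.applies_to


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters for one recording.

    Defaults follow the study protocol: 2000 Hz sampling, 30 tapping cycles
    at a 1.5 taps/s metronome tempo.  ``duration_jitter`` is the relative
    standard deviation of the (log-normal) inter-contact interval,
    ``amplitude_cv`` the relative std of the per-stroke, per-channel
    amplitude factors, and ``noise_std`` the Gaussian sensor-noise std on the
    motion channels (same acceleration units as the amplitudes).
    ``dwell_fraction`` is the share of each inter-contact interval the finger
    rests on the pad before moving.

    Stroke-to-stroke variability is deliberately high-rank: besides the
    per-channel scale factor, each stroke receives a smooth random shape
    perturbation (``n_shape_modes`` Gaussian bumps over the motion phase
    with iid coefficients of std ``shape_cv`` times the channel's peak
    acceleration).  A pure scale factor would give every channel a rank-one
    inter-trial covariance, which is not what repeated human movements look
    like and would leave the ProMP weight covariance degenerate.
    """

    sampling_rate: float = 2000.0
    n_cycles: int = 30
    tempo: float = 1.5
    stroke_amplitude: tuple[float, ...] = tuple(DEFAULT_AMPLITUDES)
    duration_jitter: float = 0.05
    amplitude_cv: float = 0.10
    shape_cv: float = 0.08
    n_shape_modes: int = 8
    dwell_fraction: float = 0.2
    noise_std: float = 0.2
    pad_pulse_duration: float = 0.02
    pad_pulse_amplitude: float = 1.0
    effect: StimulationEffect | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.tempo <= 0:
            raise ValueError("tempo must be positive")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        if min(self.duration_jitter, self.amplitude_cv, self.shape_cv) < 0:
            raise ValueError("variability parameters must be >= 0")
        if self.n_shape_modes < 2:
            raise ValueError("n_shape_modes must be >= 2")
        if not (0.0 <= self.dwell_fraction < 1.0):
            raise ValueError("dwell_fraction must be in [0, 1)")
        if len(self.stroke_amplitude) != N_MOTION:
            raise ValueError(f"stroke_amplitude needs {N_MOTION} entries")

    @property
    def amplitudes(self) -> np.ndarray:
        return np.asarray(self.stroke_amplitude, dtype=float)


@dataclass(frozen=True)
class AnomalySpec:
    """A sensor-misplacement anomaly targeting exactly one recording.

    ``axis_flip`` negates the named channels; ``axis_swap`` exchanges
    consecutive channel pairs (e.g. hand_x <-> wrist_x).
    """

    participant: int
    stimulation: str
    phase: str
    experiment: int
    kind: str  # "axis_swap" | "axis_flip"
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("axis_swap", "axis_flip"):
            raise ValueError("kind must be 'axis_swap' or 'axis_flip'")
        if self.kind == "axis_swap" and len(self.channels) % 2:
            raise ValueError("axis_swap needs an even number of channels")
        if not self.channels:
            raise ValueError("channels must be non-empty")

    @property
    def target(self) -> tuple[int, str, str, int]:
        return (self.participant, self.stimulation, self.phase, self.experiment)


@dataclass(frozen=True)
class StudyDesign:
    """Participants x stimulations x phases x experiments enumeration.

    The default reproduces the protocol: 10 participants, four stimulation
    conditions (Sham and the three active ones), five recording phases
    (familiarization, pre-stimulation baseline, three post-stimulation runs)
    and eight tapping patterns, i.e. 10*4*5*8 = 1,600 recordings.
    """

    n_participants: int = 10
    stimulations: tuple[str, ...] = STIMULATIONS
    phases: tuple[str, ...] = PHASES
    n_experiments: int = 8
    anomalies: tuple[AnomalySpec, ...] = ()

    def __post_init__(self) -> None:
        if min(self.n_participants, self.n_experiments) < 1:
            raise ValueError("all design counts must be >= 1")
        if not self.stimulations or not self.phases:
            raise ValueError("all design counts must be >= 1")
        targets = [a.target for a in self.anomalies]
        if len(targets) != len(set(targets)):
            raise ValueError("duplicate anomaly targets")
        cells = set(self.cells())
        for a in self.anomalies:
            if a.target not in cells:
                raise ValueError(f"anomaly target {a.target} not in the design")

    @property
    def n_cells(self) -> int:
        return (
            self.n_participants
            * len(self.stimulations)
            * len(self.phases)
            * self.n_experiments
        )

    def cells(self) -> Iterator[tuple[int, str, str, int]]:
        """Yield (participant, stimulation, phase, experiment) for every cell."""
        for q in range(1, self.n_participants + 1):
            for s in self.stimulations:
                for o in self.phases:
                    for p in range(1, self.n_experiments + 1):
                        yield (q, s, o, p)


def experiment_attributes(p: int) -> dict:
    """Tapping-pattern attributes of unit experiment ``p`` (1-based).

    The eight patterns combine tapping axis (left-right vs
    anterior-posterior), speed (rhythmic at the metronome tempo vs rapid at
    twice the tempo) and hand (right vs left).
    """
    i = int(p) - 1
    return {
        "axis": ("left-right", "anterior-posterior")[i % 2],
        "speed": ("rhythmic", "rapid")[(i // 2) % 2],
        "hand": ("right", "left")[(i // 4) % 2],
    }


def _cell_rng(seed: int, q: int, s: str, o: str, p: int) -> np.random.Generator:
    """Per-recording substream: stable under design reordering/subsetting."""
    entropy = [int(seed) & 0x7FFFFFFF] + [
        zlib.crc32(str(x).encode()) for x in ("cell", q, s, o, p)
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _participant_factor(seed: int, q: int) -> float:
    """Mild stable inter-subject amplitude scaling (~10% CV)."""
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [int(seed) & 0x7FFFFFFF, zlib.crc32(f"participant{q}".encode())]
        )
    )
    return float(np.clip(1.0 + 0.1 * rng.standard_normal(), 0.5, 1.5))


def segment_template(
    z,
    direction: str,
    amplitudes: np.ndarray,
    dwell_fraction: float,
    effect: StimulationEffect | None = None,
    phase_label: str | None = None,
) -> np.ndarray:
    """Noiseless 6-channel acceleration of one inter-contact segment.

    ``z`` is the segment's movement phase in [0, 1]: the finger dwells on the
    pad for ``z < dwell_fraction`` (zero acceleration) and then performs the
    minimum-jerk stroke.  Outward strokes are the time-reversed, sign-flipped
    counterpart of inward strokes, so mirrored statistics hold by
    construction.  A stimulation ``effect`` (if it applies to
    ``phase_label``) scales the template and adds its mean shift wherever
    ``z`` lies inside the effect's phase support.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    z = np.atleast_1d(np.asarray(z, dtype=float))
    u = np.clip((z - dwell_fraction) / (1.0 - dwell_fraction), 0.0, 1.0)
    moving = z >= dwell_fraction
    if direction == INWARD:
        a = minimum_jerk_acceleration(u)
    else:
        a = -minimum_jerk_acceleration(1.0 - u)
    a = np.where(moving, a, 0.0)
    out = a[:, None] * np.asarray(amplitudes, dtype=float)[None, :]
    if effect is not None and effect.applies(phase_label):
        out = out * effect.amplitude_scale
        lo, hi = effect.phase_support
        in_support = (z >= lo) & (z <= hi)
        out = out + in_support[:, None] * np.asarray(effect.mean_shift)[None, :]
    return out


def _lognormal_durations(rng, nominal: float, rel_std: float, n: int) -> np.ndarray:
    """Mean-preserving log-normal durations with relative std ``rel_std``."""
    if rel_std == 0:
        return np.full(n, nominal)
    sigma = np.sqrt(np.log1p(rel_std**2))
    return nominal * np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n))


def _stroke_amplitudes(rng, config: SyntheticConfig) -> np.ndarray:
    """Per-stroke, per-channel amplitude draw around the template amplitude."""
    factors = 1.0 + config.amplitude_cv * rng.standard_normal(N_MOTION)
    return config.amplitudes * np.clip(factors, 0.05, None)


def _draw_shape_coeffs(rng, config: SyntheticConfig) -> np.ndarray:
    """Per-stroke coefficients of the smooth shape perturbation, (K, 6)."""
    scale = config.shape_cv * config.amplitudes * TEMPLATE_PEAK_FACTOR
    return rng.standard_normal((config.n_shape_modes, N_MOTION)) * scale[None, :]


def _shape_perturbation(z, coeffs: np.ndarray, dwell_fraction: float) -> np.ndarray:
    """Evaluate the shape-perturbation field on segment phases ``z``.

    Gaussian bumps live on the motion phase u; the perturbation is zero
    while the finger rests on the pad (z < dwell_fraction).
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    K = coeffs.shape[0]
    u = np.clip((z - dwell_fraction) / (1.0 - dwell_fraction), 0.0, 1.0)
    centers = np.linspace(0.0, 1.0, K)
    width = 1.0 / K
    bumps = np.exp(-((u[:, None] - centers[None, :]) ** 2) / (2.0 * width**2))
    out = bumps @ coeffs
    out[z < dwell_fraction] = 0.0
    return out


def generate_stroke_profile(
    config: SyntheticConfig,
    direction: str,
    rng: np.random.Generator,
    phase_label: str | None = None,
) -> np.ndarray:
    """One variable-length 6-channel stroke (motion part only, no dwell).

    The duration is drawn from the jittered nominal stroke duration
    ``(1 - dwell_fraction) / tempo``; the per-channel amplitudes from a
    Gaussian around the template amplitude; Gaussian sensor noise of std
    ``noise_std`` is added.  Deterministic given the generator state.
    """
    (duration,) = _lognormal_durations(
        rng, (1.0 - config.dwell_fraction) / config.tempo, config.duration_jitter, 1
    )
    n = int(round(duration * config.sampling_rate)) + 1
    if n < 2:
        raise ValueError("stroke duration too short for the sampling rate")
    amps = _stroke_amplitudes(rng, config)
    u = np.linspace(0.0, 1.0, n)
    # dwell_fraction=0 makes the segment template the bare stroke template
    profile = segment_template(u, direction, amps, 0.0, config.effect, phase_label)
    if config.shape_cv > 0:
        profile = profile + _shape_perturbation(u, _draw_shape_coeffs(rng, config), 0.0)
    if config.noise_std > 0:
        profile = profile + rng.normal(0.0, config.noise_std, size=profile.shape)
    return profile


def generate_recording(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    metadata: dict | None = None,
) -> RawRecording:
    """One continuous recording of ``n_cycles`` tapping cycles.

    The finger starts resting on pad 1 (no pulse); each cycle is an inward
    segment ending in a pad-2 contact followed by an outward segment ending
    back on pad 1, giving 2 * n_cycles contacts and therefore 2 * n_cycles
    pad pulses.  Each inter-contact segment is dwell followed by a
    minimum-jerk stroke; contacts emit a rectangular pulse on the touched
    pad.  Ground truth (contact samples, pads, segment directions and the
    noiseless per-segment parameters) is stored in ``recording.truth``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    metadata = dict(metadata or {})
    phase_label = metadata.get("phase")
    fs = config.sampling_rate
    n_segments = 2 * config.n_cycles
    durations = _lognormal_durations(
        rng, 1.0 / config.tempo, config.duration_jitter, n_segments
    )
    contact_times = np.cumsum(durations)
    contact_samples = np.round(contact_times * fs).astype(int)
    if np.any(np.diff(np.concatenate([[0], contact_samples])) < 2):
        raise ValueError("non-positive segment duration after jitter")
    tail = int(round((config.pad_pulse_duration + 0.1) * fs))
    n_total = contact_samples[-1] + tail
    time = np.arange(n_total) / fs
    motion = np.zeros((n_total, N_MOTION))
    pads = np.zeros((n_total, len(PAD_CHANNELS)))

    directions = [INWARD if k % 2 == 0 else OUTWARD for k in range(n_segments)]
    stroke_amps = np.empty((n_segments, N_MOTION))
    starts = np.concatenate([[0], contact_samples[:-1]])
    for k in range(n_segments):
        s, e = starts[k], contact_samples[k]
        amps = _stroke_amplitudes(rng, config)
        stroke_amps[k] = amps
        zseg = (np.arange(s, e) - s) / (e - s)
        motion[s:e] = segment_template(
            zseg, directions[k], amps, config.dwell_fraction, config.effect, phase_label
        )
        if config.shape_cv > 0:
            motion[s:e] += _shape_perturbation(
                zseg, _draw_shape_coeffs(rng, config), config.dwell_fraction
            )
    if config.noise_std > 0:
        motion += rng.normal(0.0, config.noise_std, size=motion.shape)

    pulse_len = max(1, int(round(config.pad_pulse_duration * fs)))
    contact_pads = [2 if k % 2 == 0 else 1 for k in range(n_segments)]
    for k in range(n_segments):
        s = contact_samples[k]
        pads[s : s + pulse_len, contact_pads[k] - 1] = config.pad_pulse_amplitude

    truth = {
        "contact_samples": contact_samples,
        "contact_pads": np.array(contact_pads),
        "segment_directions": directions,
        "stroke_amplitudes": stroke_amps,
        "dwell_fraction": config.dwell_fraction,
    }
    return RawRecording(fs, time, motion, pads, metadata, truth)


def inject_anomaly(recording: RawRecording, spec: AnomalySpec) -> RawRecording:
    """Apply a sensor-misplacement anomaly; all other channels untouched.

    Both kinds are involutions: applying the same spec twice restores the
    input.
    """
    for name in spec.channels:
        if name not in MOTION_CHANNELS:
            raise ValueError(f"unknown motion channel {name!r}")
    motion = recording.motion.copy()
    idx = [MOTION_CHANNELS.index(c) for c in spec.channels]
    if spec.kind == "axis_flip":
        motion[:, idx] *= -1.0
    else:  # axis_swap on consecutive pairs
        for a, b in zip(idx[0::2], idx[1::2]):
            motion[:, [a, b]] = motion[:, [b, a]]
    meta = dict(recording.metadata)
    meta.setdefault("anomalies", []).append((spec.kind, spec.channels))
    return RawRecording(
        recording.sampling_rate,
        recording.time.copy(),
        motion,
        recording.pads.copy(),
        meta,
        recording.truth,
    )


def _cell_config(
    design_seed: int, config: SyntheticConfig, q: int, s: str, o: str, p: int
) -> SyntheticConfig:
    """Specialize the base config for one study cell."""
    attrs = experiment_attributes(p)
    amps = config.amplitudes * _participant_factor(design_seed, q)
    if attrs["axis"] == "anterior-posterior":
        # tapping along the other horizontal axis: swap x and y amplitudes
        amps = amps[[1, 0, 2, 4, 3, 5]]
    tempo = config.tempo * (2.0 if attrs["speed"] == "rapid" else 1.0)
    return replace(config, stroke_amplitude=tuple(amps), tempo=tempo)


def iter_study(
    design: StudyDesign, config: SyntheticConfig, seed: int
) -> Iterator[tuple[tuple[int, str, str, int], RawRecording]]:
    """Yield (cell, recording) for every design cell, streaming.

    Use this instead of :func:`generate_study` when the study is too large to
    hold in memory at once.
    """
    anomalies = {a.target: a for a in design.anomalies}
    for cell in design.cells():
        q, s, o, p = cell
        rng = _cell_rng(seed, q, s, o, p)
        cfg = _cell_config(seed, config, q, s, o, p)
        meta = {
            "participant": q,
            "stimulation": s,
            "phase": o,
            "experiment": p,
            **experiment_attributes(p),
        }
        rec = generate_recording(cfg, rng, meta)
        if cell in anomalies:
            rec = inject_anomaly(rec, anomalies[cell])
        yield cell, rec


def generate_study(
    design: StudyDesign, config: SyntheticConfig, seed: int
) -> tuple[dict[tuple[int, str, str, int], RawRecording], pd.DataFrame]:
    """All study recordings plus a manifest (one row per recording)."""
    recordings = dict(iter_study(design, config, seed))
    manifest = pd.DataFrame(
        [
            {"participant": q, "stimulation": s, "phase": o, "experiment": p}
            for (q, s, o, p) in recordings
        ]
    )
    return recordings, manifest


def sample_strokeset(
    config: SyntheticConfig,
    n: int,
    direction: str,
    grid: PhaseGrid,
    rng: np.random.Generator,
    phase_label: str | None = None,
    metadata: dict | None = None,
) -> StrokeSet:
    """Draw n phase-normalized stroke segments directly on ``grid``.

    Shortcut that emulates what (generate_recording -> detect_taps ->
    segment_strokes -> normalize_time) produces for one direction, without
    the continuous-signal round trip: each stroke is the dwell+stroke segment
    template with per-stroke amplitude jitter plus sensor noise evaluated at
    the grid phases.  Used for focused statistical tests of the model and
    divergence stages.
    """
    data = np.empty((n, grid.T, N_MOTION))
    for j in range(n):
        amps = _stroke_amplitudes(rng, config)
        data[j] = segment_template(
            grid.z, direction, amps, config.dwell_fraction, config.effect, phase_label
        )
        if config.shape_cv > 0:
            data[j] += _shape_perturbation(
                grid.z, _draw_shape_coeffs(rng, config), config.dwell_fraction
            )
    if config.noise_std > 0:
        data += rng.normal(0.0, config.noise_std, size=data.shape)
    return StrokeSet(data, direction, grid, dict(metadata or {}))
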