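"""Segmentation and phase normalization of continuous tapping recordings.

A recording is turned into two aligned :class:`~tapromp.core.StrokeSet`
objects (inward and outward strokes) on a common phase grid:

1. :func:`detect_taps` finds pad contacts from the touch-pad accelerometers
   (relative-threshold crossing with a refractory window);
2. :func:`segment_strokes` cuts the motion channels at consecutive contacts
   and labels each stroke inward or outward from the pad order;
3. :func:`select_strokes` keeps the 20 strokes from the last twenty-first to
   the last-but-one, discarding the final stroke (subjects react to the stop
   signal) and the early, tempo-settling ones;
4. :func:`normalize_time` maps each stroke onto the shared phase grid by
   linear interpolation of its [0, 1]-rescaled time axis.

An optional zero-phase low-pass filter (:func:`lowpass_filter`) can be
applied first; the default pipeline fits raw acceleration, since the basis
function expansion itself suppresses high-frequency noise.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .core import (
    INWARD,
    OUTWARD,
    PAD_CHANNELS,
    PhaseGrid,
    RawRecording,
    Stroke,
    StrokeSet,
    TapEvent,
)

__all__ = [
    "detect_taps",
    "segment_strokes",
    "select_strokes",
    "normalize_time",
    "lowpass_filter",
    "preprocess_recording",
    "DEFAULT_DIRECTION_CONVENTION",
    "N_SELECTED_STROKES",
]

# Movement direction from the traversed pad pair. Anatomically, "inward"
# means the elbow angle decreases during the stroke; which pad order that
# corresponds to depends on the pad layout and the hand used, so the map is
# configurable per experiment. The default matches the synthetic generator
# (pad 1 -> pad 2 is inward).
DEFAULT_DIRECTION_CONVENTION: Mapping[tuple[int, int], str] = {
    (1, 2): INWARD,
    (2, 1): OUTWARD,
}

# Strokes kept for model fitting per direction (protocol choice).
N_SELECTED_STROKES = 20


def detect_taps(
    recording: RawRecording,
    threshold: float = 0.5,
    refractory: float = 0.1,
) -> list[TapEvent]:
    """Detect pad contacts as threshold crossings of the pad accelerometers.

    For each pad channel, an event is the first sample where the absolute
    signal reaches ``threshold`` times the channel's absolute maximum;
    re-crossings within ``refractory`` seconds are suppressed.  Events from
    both pads are merged and returned in time order.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be a fraction in (0, 1)")
    if refractory <= 0:
        raise ValueError("refractory must be positive")
    refr = max(1, int(round(refractory * recording.sampling_rate)))
    events: list[TapEvent] = []
    for pad_id, name in enumerate(PAD_CHANNELS, start=1):
        x = np.abs(recording.channel(name))
        peak = x.max() if x.size else 0.0
        if peak <= 0:
            raise ValueError(f"no taps detected: pad channel {name!r} is flat")
        above = np.flatnonzero(x >= threshold * peak)
        last = -refr - 1
        for i in above:
            if i > last + refr:
                events.append(
                    TapEvent(int(i), pad_id, float(recording.time[i]))
                )
                last = i
    events.sort(key=lambda e: e.sample_index)
    return events


def _merge_same_pad_runs(events: Sequence[TapEvent]) -> list[TapEvent]:
    """Keep the first event of any same-pad run (double contacts)."""
    merged: list[TapEvent] = []
    dropped = 0
    for ev in events:
        if merged and ev.pad_id == merged[-1].pad_id:
            dropped += 1
            continue
        merged.append(ev)
    if dropped:
        warnings.warn(
            f"dropped {dropped} non-alternating tap event(s) (double contacts)",
            stacklevel=3,
        )
    return merged


def segment_strokes(
    recording: RawRecording,
    events: Sequence[TapEvent],
    direction_convention: Mapping[tuple[int, int], str] = DEFAULT_DIRECTION_CONVENTION,
) -> tuple[list[Stroke], list[Stroke]]:
    """Cut the recording into strokes at consecutive tap events.

    Each consecutive event pair delimits one stroke over the source interval
    ``[start, end)``; K+1 alternating events yield K strokes with
    alternating directions.  Same-pad runs (double taps) are reduced to
    their first event with a warning.  Returns ``(inward, outward)`` lists.
    """
    events = _merge_same_pad_runs(list(events))
    if len(events) < 2:
        raise ValueError("need at least two tap events to segment strokes")
    inward: list[Stroke] = []
    outward: list[Stroke] = []
    for a, b in zip(events[:-1], events[1:]):
        key = (a.pad_id, b.pad_id)
        try:
            direction = direction_convention[key]
        except KeyError:
            raise ValueError(f"direction convention has no entry for pads {key}")
        stroke = Stroke(
            recording.motion[a.sample_index : b.sample_index],
            direction,
            a.sample_index,
            b.sample_index,
        )
        (inward if direction == INWARD else outward).append(stroke)
    return inward, outward


def select_strokes(
    strokes: Sequence[Stroke], n_select: int = N_SELECTED_STROKES
) -> list[Stroke]:
    """Keep ``n_select`` strokes ending at the last-but-one stroke.

    Of K strokes (0-based indices 0..K-1) the returned window is
    ``[K - n_select - 1, K - 2]`` inclusive: the final stroke is excluded and
    the earliest strokes (before the subject settles into the tempo) are
    dropped.  Requires at least ``n_select + 1`` strokes.
    """
    K = len(strokes)
    if K < n_select + 1:
        raise ValueError(
            f"need at least {n_select + 1} strokes to select {n_select}, got {K}"
            f" ({n_select + 1 - K} short)"
        )
    return list(strokes[K - n_select - 1 : K - 1])


def normalize_time(stroke: Stroke, grid: PhaseGrid) -> np.ndarray:
    """Resample one stroke onto the phase grid, channel by channel.

    The stroke's own time axis is rescaled to [0, 1] and each channel is
    linearly interpolated at the grid phases; endpoints are preserved
    exactly, and a stroke already sampled at the grid phases passes through
    unchanged.
    """
    if not np.all(np.isfinite(stroke.samples)):
        raise ValueError("stroke contains non-finite samples")
    L = stroke.n_samples
    x = np.linspace(0.0, 1.0, L)
    out = np.empty((grid.T, stroke.samples.shape[1]))
    for d in range(stroke.samples.shape[1]):
        out[:, d] = np.interp(grid.z, x, stroke.samples[:, d])
    return out


def lowpass_filter(
    recording: RawRecording, cutoff: float, order: int = 4
) -> RawRecording:
    """Zero-phase Butterworth low-pass on the motion channels only.

    The pad channels are left untouched (their sharp pulses are what the tap
    detector relies on).  ``cutoff`` is in Hz and must lie below the Nyquist
    frequency.
    """
    if not (0.0 < cutoff < recording.sampling_rate / 2.0):
        raise ValueError("cutoff must lie in (0, sampling_rate / 2)")
    sos = signal.butter(
        order, cutoff, btype="low", fs=recording.sampling_rate, output="sos"
    )
    motion = signal.sosfiltfilt(sos, recording.motion, axis=0)
    return RawRecording(
        recording.sampling_rate,
        recording.time.copy(),
        np.ascontiguousarray(motion),
        recording.pads.copy(),
        dict(recording.metadata),
        recording.truth,
    )


def preprocess_recording(
    recording: RawRecording,
    grid: PhaseGrid,
    threshold: float = 0.5,
    refractory: float = 0.1,
    direction_convention: Mapping[tuple[int, int], str] = DEFAULT_DIRECTION_CONVENTION,
    n_select: int = N_SELECTED_STROKES,
    lowpass_cutoff: float | None = None,
) -> dict[str, StrokeSet]:
    """Full chain: taps -> strokes -> selection -> normalization.

    Returns one StrokeSet per direction.  Raises if either direction has too
    few strokes for the selection rule; callers that tolerate missing cells
    catch that.
    """
    if lowpass_cutoff is not None:
        recording = lowpass_filter(recording, lowpass_cutoff)
    events = detect_taps(recording, threshold, refractory)
    inward, outward = segment_strokes(recording, events, direction_convention)
    sets: dict[str, StrokeSet] = {}
    for direction, strokes in ((INWARD, inward), (OUTWARD, outward)):
        chosen = select_strokes(strokes, n_select)
        data = np.stack([normalize_time(st, grid) for st in chosen])
        sets[direction] = StrokeSet(
            data, direction, grid, dict(recording.metadata)
        )
    return sets
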