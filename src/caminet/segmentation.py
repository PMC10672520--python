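"""Active-state segmentation of calcium traces.

A neuron is "active" while its fluorescence rises faster than an adaptive
threshold.  The pipeline per trace is

1. moving-average smoothing (window ``wnd_size`` frames, edge-truncated),
2. discrete derivative ``x'_t = x_t - x_{t-1}``,
3. threshold ``median(x') + mad(x')`` with ``mad`` the mean absolute
   deviation about the median,
4. frames with derivative strictly above the threshold form *spike*
   intervals; in *full* mode each is extended forward through the decay
   until the smoothed intensity falls back to its onset level,
5. warm/cold refinement: gaps shorter than ``warm`` frames are merged,
   then intervals shorter than ``cold`` frames are dropped.

The adaptive threshold is computed per unit and per recording, never
globally: it tracks each neuron's own noise floor.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import ActivityMask, Interval, Recording, SegmentationParams, binary_to_intervals

__all__ = [
    "smooth",
    "derivative",
    "adaptive_threshold",
    "refine",
    "segment",
    "segment_recording",
]


def smooth(trace: np.ndarray, wnd_size: int) -> np.ndarray:
    """Centered moving average of width ``wnd_size``.

    The window spans ``t - wnd_size//2 .. t + wnd_size//2``; at the series
    edges it is truncated and renormalized by the number of samples actually
    covered, so a constant series maps to itself and the output has the
    input's length.  ``wnd_size == 1`` is the identity.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or trace.size < 1:
        raise ValueError("trace must be a non-empty 1-D series")
    if wnd_size < 1:
        raise ValueError("wnd_size must be >= 1")
    half = wnd_size // 2
    if half == 0:
        return trace.copy()
    kernel = np.ones(2 * half + 1)
    num = np.convolve(trace, kernel, mode="same")
    den = np.convolve(np.ones_like(trace), kernel, mode="same")
    return num / den


def derivative(trace: np.ndarray) -> np.ndarray:
    """Frame-to-frame difference; element 0 is defined as 0 so the output
    keeps the input's length."""
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or trace.size < 2:
        raise ValueError("derivative needs a 1-D series of length >= 2")
    d = np.empty_like(trace)
    d[0] = 0.0
    d[1:] = np.diff(trace)
    return d


def adaptive_threshold(deriv: np.ndarray) -> float:
    """``median(deriv) + mad(deriv)`` where mad is the mean absolute
    deviation about the median."""
    deriv = np.asarray(deriv, dtype=float)
    if deriv.ndim != 1 or deriv.size < 2:
        raise ValueError("threshold needs a 1-D series of length >= 2")
    med = float(np.median(deriv))
    mad = float(np.mean(np.abs(deriv - med)))
    return med + mad


def refine(intervals: Sequence[Interval], warm: int, cold: int) -> list[Interval]:
    """Warm/cold cleanup of a sorted, disjoint interval list.

    First any gap strictly shorter than ``warm`` frames between consecutive
    intervals is merged; then any resulting interval strictly shorter than
    ``cold`` frames is dropped.  ``warm == cold == 0`` is the identity.
    """
    merged: list[Interval] = []
    for s, e in intervals:
        if merged and s - merged[-1][1] < warm:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((int(s), int(e)))
    return [(s, e) for s, e in merged if e - s >= max(cold, 1)]


def segment(
    trace: np.ndarray,
    params: SegmentationParams | None = None,
    fps: float | None = None,
) -> tuple[list[Interval], np.ndarray]:
    """Segment one trace into active intervals plus the equivalent binary series.

    Returns ``(intervals, binary)``; intervals are half-open frame index
    pairs.  ``fps`` is accepted for interface symmetry (the rules operate
    purely in frames).
    """
    if params is None:
        params = SegmentationParams()
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2:
        raise ValueError("segment needs at least 2 frames")
    smoothed = smooth(trace, params.wnd_size)
    d = derivative(smoothed)
    thr = adaptive_threshold(d)
    spikes = binary_to_intervals(d > thr)

    if params.mode == "full":
        extended: list[Interval] = []
        for i, (s, e) in enumerate(spikes):
            cap = spikes[i + 1][0] if i + 1 < len(spikes) else len(trace)
            t = e
            # follow the decay until intensity returns to its onset level
            while t < cap and smoothed[t] > smoothed[s]:
                t += 1
            extended.append((s, t))
        # extension may run up against the next onset: merge touching runs
        spikes = refine(extended, warm=1, cold=0)

    intervals = refine(spikes, params.warm, params.cold)
    binary = np.zeros(trace.size, dtype=bool)
    for s, e in intervals:
        binary[s:e] = True
    return intervals, binary


def segment_recording(rec: Recording, params: SegmentationParams | None = None) -> ActivityMask:
    """Apply :func:`segment` to every unit of a recording."""
    if params is None:
        params = SegmentationParams()
    traces = rec.traces.intensities
    all_intervals: list[list[Interval]] = []
    active = np.zeros(traces.shape, dtype=bool)
    for i in range(traces.shape[0]):
        try:
            ivs, binary = segment(traces[i], params, rec.fps)
        except ValueError as err:
            raise ValueError(f"unit {rec.traces.unit_ids[i]}: {err}") from err
        all_intervals.append(ivs)
        active[i] = binary
    return ActivityMask(active=active, intervals=all_intervals, unit_ids=rec.traces.unit_ids.copy())


def intervals_table(mask: ActivityMask, fps: float):
    """Per-unit interval list as a tidy table (unit_id, start/end frame and seconds)."""
    import pandas as pd

    rows = []
    for uid, ivs in zip(mask.unit_ids, mask.intervals):
        for s, e in ivs:
            rows.append((int(uid), s, e, s / fps, e / fps))
    return pd.DataFrame(rows, columns=["unit_id", "start_frame", "end_frame", "start_s", "end_s"])
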