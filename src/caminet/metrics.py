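"""Single-neuron and network activity metrics computed from an ActivityMask.

* burst rate — per-neuron count of distinct active states per minute;
* network spike rate (NSR) — per-window percentage of units active at
  least once in the window;
* network spike peak (NSP) — per-window maximum percentage of
  simultaneously active units;
* network spike duration (NSD) — percentage of recording time during which
  the simultaneously-active fraction strictly exceeds a threshold.

Windows tile the recording consecutively without overlap.  A trailing
partial window is kept when it covers at least half a window, otherwise
dropped.
"""

from __future__ import annotations

import numpy as np

from .core import ActivityMask, MetricConfig

__all__ = [
    "window_bounds",
    "burst_rate",
    "network_spike_rate",
    "network_spike_peak",
    "network_spike_duration",
]


def window_bounds(n_frames: int, interval_s: float, fps: float) -> list[tuple[int, int]]:
    """Half-open frame windows tiling the recording.

    Window length is ``round(interval_s * fps)`` frames; the trailing
    partial window is included iff it is at least half a window long.
    """
    w = int(round(interval_s * fps))
    if w < 1:
        raise ValueError("window shorter than one frame")
    if w > n_frames:
        raise ValueError(f"window of {w} frames exceeds recording length {n_frames}")
    bounds = []
    for start in range(0, n_frames, w):
        end = min(start + w, n_frames)
        if end - start < w and 2 * (end - start) < w:
            break
        bounds.append((start, end))
    return bounds


def burst_rate(mask: ActivityMask, fps: float) -> np.ndarray:
    """Activations per minute for each unit (count of active intervals
    divided by recording duration in minutes)."""
    if mask.n_frames < 1:
        raise ValueError("empty recording")
    minutes = mask.n_frames / fps / 60.0
    if minutes <= 0:
        raise ValueError("zero-length recording")
    return np.array([len(ivs) for ivs in mask.intervals], dtype=float) / minutes


def network_spike_rate(mask: ActivityMask, cfg: MetricConfig | None = None, fps: float = 20.0) -> np.ndarray:
    """Per-window percentage of units with at least one active frame in the window."""
    cfg = cfg or MetricConfig()
    bounds = window_bounds(mask.n_frames, cfg.interval_s, fps)
    vals = [100.0 * mask.active[:, a:b].any(axis=1).mean() for a, b in bounds]
    return np.asarray(vals)


def network_spike_peak(mask: ActivityMask, cfg: MetricConfig | None = None, fps: float = 20.0) -> np.ndarray:
    """Per-window maximum over frames of the simultaneously-active percentage."""
    cfg = cfg or MetricConfig()
    bounds = window_bounds(mask.n_frames, cfg.interval_s, fps)
    frac = mask.active.mean(axis=0)
    vals = [100.0 * frac[a:b].max() for a, b in bounds]
    return np.asarray(vals)


def network_spike_duration(mask: ActivityMask, cfg: MetricConfig | None = None) -> float:
    """Percentage of frames where the active fraction strictly exceeds
    ``cfg.nsd_threshold``."""
    cfg = cfg or MetricConfig()
    frac = mask.active.mean(axis=0)
    return float(100.0 * np.mean(frac > cfg.nsd_threshold))
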