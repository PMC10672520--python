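"""Synthetic calcium recordings with known ground truth.

The generator emulates the trace matrix a CNMF-style pipeline (e.g. Minian)
hands downstream: per neuron, a homogeneous-Poisson train of calcium
transients — linear rise over ``rise_frames`` then exponential decay with
time constant ``decay_tau_frames`` (a GCaMP6s-like kernel at 20 fps), with
truncated-normal amplitudes — plus a slow baseline fluctuation.  Because the
input class is *denoised* traces, the noise term is a low-frequency Gaussian
process (white Gaussian noise filtered with a Gaussian kernel of width
``noise_timescale_frames``, rescaled to ``noise_sd``); setting the timescale
to 0 gives plain white noise.  Optionally a subset of units is organized
into correlated groups sharing event onsets up to a small jitter, and every
unit receives a uniform random arena position.

Ground truth (event onsets, durations, group membership, positions) is
returned alongside the Recording so detection and correlation stages can be
scored exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import ActivityMask, NeuronPositions, Recording, TraceMatrix

__all__ = [
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "generate",
    "generate_worked_fixture",
    "score_detection",
]


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults mirror a typical 5-minute miniscope session: 100 units at
    20 fps, 2 events per minute per unit, transient amplitude 1.0 ± 0.2
    with baseline noise sd 0.1 (signal-to-noise 10) varying on a ~5 s
    timescale, in a 300-pixel arena.
    """

    n_units: int = 100
    n_frames: int = 6000
    fps: float = 20.0
    event_rate: float = 2.0  # events per minute per unit
    rise_frames: int = 5
    decay_tau_frames: float = 40.0
    amplitude_mean: float = 1.0
    amplitude_sd: float = 0.2
    noise_sd: float = 0.1
    noise_timescale_frames: float = 100.0
    n_correlated_groups: int = 0
    group_size: int = 10
    within_group_jitter_frames: int = 2
    arena_size_px: float = 300.0
    drift_per_minute: float = 0.0  # linear baseline drift, fluorescence units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1 or self.n_frames < 2:
            raise ValueError("need n_units >= 1 and n_frames >= 2")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        for name in ("event_rate", "decay_tau_frames", "amplitude_sd", "noise_sd",
                     "noise_timescale_frames", "arena_size_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rise_frames < 1:
            raise ValueError("rise_frames must be >= 1")
        if self.n_correlated_groups < 0 or self.within_group_jitter_frames < 0:
            raise ValueError("group settings must be >= 0")
        if self.n_correlated_groups * self.group_size > self.n_units:
            raise ValueError("correlated groups exceed the number of units")


@dataclass
class SyntheticGroundTruth:
    """Planted events and layout: per unit the event onset frames and
    durations (rise + decay-to-5% extent), group id (-1 = independent),
    and the true positions."""

    onsets: list[np.ndarray]
    durations: list[np.ndarray]
    group: np.ndarray
    positions: NeuronPositions


def _kernel(rise: int, tau: float, amp: float, max_len: int) -> np.ndarray:
    ramp = amp * np.arange(1, rise + 1) / rise
    if tau > 0:
        n_dec = min(int(np.ceil(3 * tau)), max(max_len - rise, 0))
        decay = amp * np.exp(-np.arange(1, n_dec + 1) / tau)
    else:
        decay = np.zeros(0)
    return np.concatenate([ramp, decay])[:max_len]


def _slow_noise(rng: np.random.Generator, n: int, sd: float, timescale: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    raw = rng.standard_normal(n)
    if timescale > 0:
        raw = gaussian_filter1d(raw, timescale, mode="reflect")
        s = raw.std()
        if s > 0:
            raw = raw / s
    return raw * sd


def generate(cfg: SyntheticConfig) -> tuple[Recording, SyntheticGroundTruth]:
    """Draw one synthetic recording plus its ground truth, reproducibly
    from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    minutes = cfg.n_frames / cfg.fps / 60.0
    lam = cfg.event_rate * minutes
    max_onset = cfg.n_frames - cfg.rise_frames
    if max_onset < 1:
        raise ValueError("recording too short for a single transient")

    group = np.full(cfg.n_units, -1, dtype=int)
    for g in range(cfg.n_correlated_groups):
        group[g * cfg.group_size : (g + 1) * cfg.group_size] = g
    group_templates = {
        g: np.sort(rng.integers(0, max_onset, size=rng.poisson(lam)))
        for g in range(cfg.n_correlated_groups)
    }

    capacity = cfg.n_frames // (cfg.rise_frames + 1)
    traces = np.zeros((cfg.n_units, cfg.n_frames))
    onsets_all: list[np.ndarray] = []
    durations_all: list[np.ndarray] = []
    for u in range(cfg.n_units):
        if group[u] >= 0:
            base = group_templates[group[u]]
            j = cfg.within_group_jitter_frames
            onsets = base + rng.integers(-j, j + 1, size=len(base)) if j else base.copy()
            onsets = np.clip(onsets, 0, max_onset - 1)
        else:
            k = rng.poisson(lam)
            onsets = rng.integers(0, max_onset, size=k)
        onsets = np.sort(onsets)
        if len(onsets) > capacity:
            warnings.warn(f"unit {u}: event rate infeasible, thinning {len(onsets)} -> {capacity} events")
            onsets = np.sort(rng.choice(onsets, size=capacity, replace=False))
        durs = np.empty(len(onsets), dtype=int)
        for i, o in enumerate(onsets):
            amp = max(rng.normal(cfg.amplitude_mean, cfg.amplitude_sd), 0.0)
            ker = _kernel(cfg.rise_frames, cfg.decay_tau_frames, amp, cfg.n_frames - o)
            traces[u, o : o + len(ker)] += ker
            durs[i] = len(ker)
        onsets_all.append(onsets)
        durations_all.append(durs)
        traces[u] += _slow_noise(rng, cfg.n_frames, cfg.noise_sd, cfg.noise_timescale_frames)
        if cfg.drift_per_minute:
            traces[u] += cfg.drift_per_minute * np.arange(cfg.n_frames) / (cfg.fps * 60.0)

    positions = NeuronPositions(
        unit_ids=np.arange(cfg.n_units),
        x=rng.uniform(0, cfg.arena_size_px, cfg.n_units),
        y=rng.uniform(0, cfg.arena_size_px, cfg.n_units),
    )
    rec = Recording(
        traces=TraceMatrix(intensities=traces, fps=cfg.fps, unit_ids=np.arange(cfg.n_units)),
        positions=positions,
        name=f"synthetic_seed{cfg.seed}",
    )
    gt = SyntheticGroundTruth(
        onsets=onsets_all, durations=durations_all, group=group, positions=positions
    )
    return rec, gt


def generate_worked_fixture() -> tuple[Recording, SyntheticGroundTruth]:
    """Tiny deterministic 3-unit, 200-frame recording with hand-checkable
    segmentation: unit 0 has one noiseless transient (one detected
    interval), unit 1 is flat (none), unit 2 has two transients whose gap
    is shorter than the default warm so they merge into one interval."""
    n_frames = 200
    rise, tau = 5, 5.0
    traces = np.zeros((3, n_frames))
    onsets = [np.array([80]), np.array([], dtype=int), np.array([60, 76])]
    durations: list[np.ndarray] = []
    for u, ons in enumerate(onsets):
        durs = np.empty(len(ons), dtype=int)
        for i, o in enumerate(ons):
            ker = _kernel(rise, tau, 1.0, n_frames - o)
            traces[u, o : o + len(ker)] += ker
            durs[i] = len(ker)
        durations.append(durs)
    positions = NeuronPositions(unit_ids=np.arange(3), x=np.array([0.0, 10.0, 20.0]), y=np.zeros(3))
    rec = Recording(
        traces=TraceMatrix(intensities=traces, fps=20.0, unit_ids=np.arange(3)),
        positions=positions,
        name="worked_fixture",
    )
    gt = SyntheticGroundTruth(
        onsets=onsets, durations=durations, group=np.full(3, -1), positions=positions
    )
    return rec, gt


def score_detection(
    gt: SyntheticGroundTruth,
    mask: ActivityMask,
    rise_frames: int = 5,
    margin: int = 7,
) -> dict[str, float]:
    """Recall and precision of detected intervals against planted onsets.

    A planted event is recovered when some detected interval overlaps its
    rise window widened by ``margin`` frames (the smoothing window shifts
    interval edges by up to half its width); a detected interval is a true
    positive when it overlaps at least one such window.
    """
    hits = events = tp = n_intervals = 0
    for ons, ivs in zip(gt.onsets, mask.intervals):
        windows = [(o - margin, o + rise_frames + margin) for o in ons]
        events += len(windows)
        n_intervals += len(ivs)
        hits += sum(any(s < we and e > ws for s, e in ivs) for ws, we in windows)
        tp += sum(any(s < we and e > ws for ws, we in windows) for s, e in ivs)
    return {
        "recall": hits / events if events else 1.0,
        "precision": tp / n_intervals if n_intervals else 1.0,
        "n_events": float(events),
        "n_intervals": float(n_intervals),
    }
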