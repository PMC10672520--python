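"""Core data containers for calcium-trace analysis.

The central objects are :class:`TraceMatrix` (per-neuron fluorescence time
series with a frame rate), :class:`NeuronPositions` (pixel centroids),
:class:`Recording` (the two bundled under a name) and :class:`ActivityMask`
(binary active/inactive state per neuron per frame plus the equivalent
interval list).  Intervals are half-open ``[start, end)`` 0-based frame
indices everywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TraceMatrix",
    "NeuronPositions",
    "Recording",
    "ActivityMask",
    "SegmentationParams",
    "MetricConfig",
    "ShuffleConfig",
    "intervals_to_binary",
    "binary_to_intervals",
]

Interval = tuple[int, int]


def binary_to_intervals(active: np.ndarray) -> list[Interval]:
    """Extract maximal runs of ``True`` as half-open ``(start, end)`` pairs."""
    b = np.asarray(active, dtype=bool).astype(np.int8)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], b, [0]))))
    return [(int(s), int(e)) for s, e in zip(edges[::2], edges[1::2])]


def intervals_to_binary(intervals: Sequence[Interval], n_frames: int) -> np.ndarray:
    """Rasterize half-open intervals onto a boolean series of length ``n_frames``."""
    out = np.zeros(n_frames, dtype=bool)
    for s, e in intervals:
        if not (0 <= s < e <= n_frames):
            raise ValueError(f"interval ({s}, {e}) outside [0, {n_frames})")
        out[s:e] = True
    return out


@dataclass
class TraceMatrix:
    """Fluorescence traces, one row per neuron, one column per frame.

    Parameters
    ----------
    intensities
        Real matrix ``(n_units, n_frames)`` in arbitrary fluorescence units.
    fps
        Acquisition frame rate in frames per second (must be positive).
    unit_ids
        Unique integer label per row.
    """

    intensities: np.ndarray
    fps: float
    unit_ids: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D (units x frames)")
        n_units, n_frames = self.intensities.shape
        if n_units < 1 or n_frames < 2:
            raise ValueError("need at least 1 unit and 2 frames")
        if not np.isfinite(self.fps) or self.fps <= 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        if self.unit_ids is None:
            self.unit_ids = np.arange(n_units)
        self.unit_ids = np.asarray(self.unit_ids, dtype=int)
        if self.unit_ids.shape != (n_units,):
            raise ValueError("unit_ids length must match number of trace rows")
        if len(np.unique(self.unit_ids)) != n_units:
            raise ValueError("unit_ids must be unique")
        if not np.isfinite(self.intensities).all():
            bad = self.unit_ids[~np.isfinite(self.intensities).all(axis=1)]
            raise ValueError(f"non-finite trace values for units {bad.tolist()}")

    @property
    def n_units(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass
class NeuronPositions:
    """Pixel coordinates of neuron centroids."""

    unit_ids: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.unit_ids = np.asarray(self.unit_ids, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.unit_ids)
        if self.x.shape != (n,) or self.y.shape != (n,):
            raise ValueError("x, y must match unit_ids in length")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("positions must be finite")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def as_array(self) -> np.ndarray:
        """``(n_units, 2)`` array of ``(x, y)`` rows."""
        return np.column_stack([self.x, self.y])


@dataclass
class Recording:
    """One imaging session: traces plus (optionally) neuron positions."""

    traces: TraceMatrix
    positions: Optional[NeuronPositions] = None
    name: str = "recording"

    def __post_init__(self) -> None:
        if self.positions is not None:
            if set(self.positions.unit_ids) != set(self.traces.unit_ids):
                raise ValueError("positions must cover exactly the trace unit_ids")
            # align position rows to trace order
            order = {u: i for i, u in enumerate(self.positions.unit_ids)}
            idx = np.array([order[u] for u in self.traces.unit_ids])
            self.positions = NeuronPositions(
                unit_ids=self.traces.unit_ids.copy(),
                x=self.positions.x[idx],
                y=self.positions.y[idx],
            )

    @property
    def fps(self) -> float:
        return self.traces.fps


@dataclass
class ActivityMask:
    """Active/inactive segmentation of every unit in a recording.

    ``active`` is a boolean ``(n_units, n_frames)`` matrix; ``intervals``
    holds, per unit, the sorted disjoint half-open frame intervals that
    rasterize to exactly that row.
    """

    active: np.ndarray
    intervals: list[list[Interval]]
    unit_ids: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.active = np.asarray(self.active, dtype=bool)
        if self.active.ndim != 2:
            raise ValueError("active must be 2-D")
        n_units, n_frames = self.active.shape
        if len(self.intervals) != n_units:
            raise ValueError("one interval list required per unit")
        if self.unit_ids is None:
            self.unit_ids = np.arange(n_units)
        self.unit_ids = np.asarray(self.unit_ids, dtype=int)
        for u, ivs in enumerate(self.intervals):
            if not np.array_equal(intervals_to_binary(ivs, n_frames), self.active[u]):
                raise ValueError(f"intervals inconsistent with binary row for unit index {u}")

    @classmethod
    def from_intervals(
        cls, intervals: Sequence[Sequence[Interval]], n_frames: int, unit_ids=None
    ) -> "ActivityMask":
        ivs = [sorted((int(s), int(e)) for s, e in unit) for unit in intervals]
        active = np.stack([intervals_to_binary(u, n_frames) for u in ivs]) if ivs else np.zeros((0, n_frames), bool)
        # canonicalize: re-extract runs so adjacent intervals merge
        ivs = [binary_to_intervals(row) for row in active]
        return cls(active=active, intervals=ivs, unit_ids=unit_ids)

    @classmethod
    def from_binary(cls, active: np.ndarray, unit_ids=None) -> "ActivityMask":
        active = np.asarray(active, dtype=bool)
        return cls(
            active=active,
            intervals=[binary_to_intervals(row) for row in active],
            unit_ids=unit_ids,
        )

    @property
    def n_units(self) -> int:
        return self.active.shape[0]

    @property
    def n_frames(self) -> int:
        return self.active.shape[1]


@dataclass
class SegmentationParams:
    """Settings for active-state segmentation.

    ``wnd_size`` is the moving-average window width in frames; ``warm`` the
    minimum passive-phase duration (shorter gaps between active states are
    merged); ``cold`` the minimum active-phase duration (shorter states are
    dropped); ``mode`` selects whether only the fluorescence rise (``spike``)
    or rise plus decay (``full``) counts as active.
    """

    wnd_size: int = 10
    warm: int = 15
    cold: int = 0
    mode: str = "spike"

    def __post_init__(self) -> None:
        if self.wnd_size < 1:
            raise ValueError("wnd_size must be >= 1")
        if self.warm < 0 or self.cold < 0:
            raise ValueError("warm and cold must be >= 0")
        if self.mode not in ("spike", "full"):
            raise ValueError(f"mode must be 'spike' or 'full', got {self.mode!r}")


@dataclass
class MetricConfig:
    """Windowing for network metrics: window length in seconds and the
    simultaneous-activity fraction defining a network spike."""

    interval_s: float = 3.0
    nsd_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.interval_s <= 0:
            raise ValueError("interval_s must be > 0")
        if not (0 < self.nsd_threshold < 1):
            raise ValueError("nsd_threshold must be in (0, 1)")


@dataclass
class ShuffleConfig:
    """Surrogate-generation settings: fraction of units shuffled per
    iteration, number of independent iterations, and the RNG seed."""

    ratio: float = 1.0
    num_of_shuffles: int = 10
    seed: int = 0
    respect_positions: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.ratio <= 1.0):
            raise ValueError("ratio must be in [0, 1]")
        if self.num_of_shuffles < 1:
            raise ValueError("num_of_shuffles must be >= 1")
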