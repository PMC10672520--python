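"""Spatial statistics on neuron centroid positions (pixel units).

Per unit: distance *rho* to the population center of mass (the polar radius
of the neuron in the recording's coordinate frame).  Per unordered pair:
the Euclidean (straight-line) distance and the radial distance
``|rho_i - rho_j|``.  A saturating distance factor ``k = d / (d + d0)``
rescales distances into [0, 1); by default ``d0`` is the 25th percentile of
the recording's own Euclidean pair-distance distribution (a fixed
``d0 = 100`` px is available for strict reproduction of reported analyses).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import ActivityMask, NeuronPositions, Recording
from .correlation import CorrelationMatrix, _pearson

__all__ = [
    "center_of_mass",
    "polar_rho",
    "pair_distances",
    "default_d0",
    "distance_factor",
    "correlation_vs_distance",
]


def center_of_mass(pos: NeuronPositions) -> tuple[float, float]:
    """Unweighted mean of the unit coordinates."""
    if pos.n_units < 1:
        raise ValueError("no units")
    return float(pos.x.mean()), float(pos.y.mean())


def polar_rho(pos: NeuronPositions) -> np.ndarray:
    """Euclidean distance of each unit to the center of mass."""
    cx, cy = center_of_mass(pos)
    return np.hypot(pos.x - cx, pos.y - cy)


def pair_distances(pos: NeuronPositions, kind: str = "euclidean") -> np.ndarray:
    """Condensed (upper-triangle) vector of pairwise distances.

    ``euclidean`` — straight-line pixel distance; ``radial`` — absolute
    difference of the two units' rho values.
    """
    if pos.n_units < 2:
        raise ValueError("pair distances need at least 2 units")
    if kind == "euclidean":
        return pdist(pos.as_array())
    if kind == "radial":
        rho = polar_rho(pos)
        return pdist(rho[:, None])
    raise ValueError(f"kind must be 'euclidean' or 'radial', got {kind!r}")


def default_d0(pos: NeuronPositions) -> float:
    """25th percentile of the Euclidean pair-distance distribution."""
    return float(np.percentile(pair_distances(pos, "euclidean"), 25))


def distance_factor(dist, d0: float):
    """Saturating distance factor ``k = dist / (dist + d0)`` in [0, 1)."""
    if d0 <= 0:
        raise ValueError("d0 must be > 0")
    dist = np.asarray(dist, dtype=float)
    if (dist < 0).any():
        raise ValueError("distances must be >= 0")
    k = dist / (dist + d0)
    return float(k) if k.ndim == 0 else k


def correlation_vs_distance(
    rec: Recording,
    mask: ActivityMask,
    corr: CorrelationMatrix,
    kind: str = "euclidean",
    d0: float | None = None,
    weight: bool = False,
) -> dict:
    """Relate co-activity and signal quality to spatial layout.

    Returns a dict with

    ``per_unit``
        table of unit_id, mean fluorescence, active-state ratio and rho;
    ``r_fluorescence_vs_rho`` / ``r_active_ratio_vs_rho``
        Pearson r of each per-unit quantity against rho (0 with a warning
        when a series has zero variance);
    ``pairs``
        one row per unordered pair: correlation r, distance of the chosen
        kind, the distance factor k and (if ``weight``) r × k.
    """
    if rec.positions is None:
        raise ValueError("distance analysis requires positions")
    pos = rec.positions
    n = pos.n_units
    if corr.n_units != n or mask.n_units != n:
        raise ValueError("unit-count mismatch between correlation, mask and positions")

    rho = polar_rho(pos)
    mean_fluor = rec.traces.intensities.mean(axis=1)
    active_ratio = mask.active.mean(axis=1)
    per_unit = pd.DataFrame(
        {
            "unit_id": rec.traces.unit_ids,
            "mean_fluorescence": mean_fluor,
            "active_ratio": active_ratio,
            "rho": rho,
        }
    )
    r_fluor = _pearson(mean_fluor, rho)
    r_ratio = _pearson(active_ratio, rho)

    dists = pair_distances(pos, kind)
    if d0 is None:
        d0 = default_d0(pos)
    k = distance_factor(dists, d0)
    iu = np.triu_indices(n, k=1)
    pairs = pd.DataFrame(
        {
            "unit_i": rec.traces.unit_ids[iu[0]],
            "unit_j": rec.traces.unit_ids[iu[1]],
            "r": corr.values[iu],
            "distance": dists,
            "k": k,
        }
    )
    if weight:
        pairs["r_weighted"] = pairs["r"] * pairs["k"]
    return {
        "per_unit": per_unit,
        "r_fluorescence_vs_rho": r_fluor,
        "r_active_ratio_vs_rho": r_ratio,
        "pairs": pairs,
        "d0": float(d0),
    }
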