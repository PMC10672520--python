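"""Pairwise co-activity analysis.

Pearson's correlation coefficient between neuron pairs, computed on one of
five representations of each neuron's activity:

``signal``
    the raw fluorescence trace;
``diff``
    its frame-to-frame derivative;
``active`` / ``full``
    the binary active-state series from spike- or full-mode segmentation;
``active_acc``
    the co-activity ratio |X ∩ Y| / (|X| + |Y|) of the two binary series
    (simultaneously-active time over summed individual active time, in
    [0, 0.5]).

An optional lag reports, per pair, the maximum Pearson coefficient over
integer shifts in ``[-lag, +lag]`` (truncated overlap); ``lag = 0`` reduces
exactly to the unshifted coefficient.

Derived network statistics: the network-degree curve (percentage of pairs
correlated above each threshold on a 0..1 grid of step 0.05), per-unit
connectivity shares, percentile-based clustering into connected components,
a plug-in transfer-entropy estimate, and scalar summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import ActivityMask, Recording

__all__ = [
    "CorrelationMatrix",
    "pearson_matrix",
    "active_acc",
    "network_degree",
    "connectivity",
    "cluster",
    "transfer_entropy",
    "transfer_entropy_matrix",
    "correlation_summary",
]

PEARSON_METHODS = ("signal", "diff", "active", "full")
METHODS = PEARSON_METHODS + ("active_acc",)

DEGREE_THRESHOLDS = np.round(np.linspace(0.0, 1.0, 21), 2)


@dataclass
class CorrelationMatrix:
    """Symmetric pairwise coefficients for one method and lag."""

    values: np.ndarray
    method: str
    lag: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("correlation matrix must be square")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    def offdiag(self) -> np.ndarray:
        """Upper-triangle off-diagonal values as a flat vector."""
        iu = np.triu_indices(self.n_units, k=1)
        return self.values[iu]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Plain Pearson r; 0 (with a warning) when either series has zero variance."""
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd * xd).sum() * (yd * yd).sum())
    if denom == 0.0:
        warnings.warn("zero-variance series in Pearson correlation; returning r = 0")
        return 0.0
    return float((xd * yd).sum() / denom)


def _lagged_pearson(x: np.ndarray, y: np.ndarray, lag: int) -> float:
    """Maximum Pearson r over integer shifts s in [-lag, +lag].

    Shift ``s > 0`` aligns ``x[t]`` with ``y[t+s]`` (y delayed by s).
    """
    if lag == 0:
        return _pearson(x, y)
    best = -np.inf
    n = len(x)
    for s in range(-lag, lag + 1):
        if s >= 0:
            xs, ys = x[: n - s] if s else x, y[s:]
        else:
            xs, ys = x[-s:], y[: n + s]
        if len(xs) < 2:
            continue
        best = max(best, _pearson(xs, ys))
    return best if np.isfinite(best) else 0.0


def active_acc(mask_x: np.ndarray, mask_y: np.ndarray) -> float:
    """Co-activity ratio: simultaneously-active frames over the sum of the
    two units' individual active durations.  Bounded by 0.5 (identical
    masks); 0 when either mask is empty."""
    mx = np.asarray(mask_x, dtype=bool)
    my = np.asarray(mask_y, dtype=bool)
    if mx.shape != my.shape:
        raise ValueError("mask length mismatch")
    denom = int(mx.sum()) + int(my.sum())
    if denom == 0:
        return 0.0
    return float((mx & my).sum() / denom)


def _lagged_active_acc(x: np.ndarray, y: np.ndarray, lag: int) -> float:
    if lag == 0:
        return active_acc(x, y)
    n = len(x)
    best = 0.0
    for s in range(-lag, lag + 1):
        if s >= 0:
            xs, ys = x[: n - s] if s else x, y[s:]
        else:
            xs, ys = x[-s:], y[: n + s]
        if len(xs) >= 1:
            best = max(best, active_acc(xs, ys))
    return best


def pearson_matrix(
    rec: Recording | None,
    mask: ActivityMask | None,
    method: str = "signal",
    lag: int = 0,
) -> CorrelationMatrix:
    """Pairwise coefficient matrix for the requested method.

    ``signal``/``diff`` need a Recording; ``active``/``full``/``active_acc``
    need an ActivityMask produced with the matching segmentation mode.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    if lag < 0:
        raise ValueError("lag must be >= 0")
    if method == "signal":
        if rec is None:
            raise ValueError("signal method requires a Recording")
        data = rec.traces.intensities
    elif method == "diff":
        if rec is None:
            raise ValueError("diff method requires a Recording")
        data = np.diff(rec.traces.intensities, axis=1)
    else:
        if mask is None:
            raise ValueError(f"{method} method requires an ActivityMask")
        data = mask.active.astype(float)
    n = data.shape[0]
    if n < 2:
        raise ValueError("need at least 2 units")

    values = np.zeros((n, n))
    if method == "active_acc":
        binary = data.astype(bool)
        for i in range(n):
            values[i, i] = active_acc(binary[i], binary[i])
        for i in range(n):
            for j in range(i + 1, n):
                r = _lagged_active_acc(binary[i], binary[j], lag)
                values[i, j] = values[j, i] = r
        return CorrelationMatrix(values=values, method=method, lag=lag)

    if lag == 0:
        # vectorized Pearson with a zero-variance guard
        sd = data.std(axis=1)
        zero = sd == 0.0
        if zero.any():
            warnings.warn(f"{int(zero.sum())} zero-variance series; their r set to 0")
        safe = np.where(zero[:, None], 0.0, data - data.mean(axis=1, keepdims=True))
        norms = np.sqrt((safe * safe).sum(axis=1))
        norms[norms == 0.0] = 1.0
        values = (safe @ safe.T) / np.outer(norms, norms)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(n):
                for j in range(i + 1, n):
                    values[i, j] = values[j, i] = _lagged_pearson(data[i], data[j], lag)
    np.fill_diagonal(values, 1.0)
    return CorrelationMatrix(values=np.clip(values, -1.0, 1.0), method=method, lag=lag)


def network_degree(corr: CorrelationMatrix, thresholds: np.ndarray | None = None):
    """Percentage of unordered pairs with r strictly above each threshold.

    Returns ``(thresholds, percent_connected)``; thresholds default to the
    0..1 grid with step 0.05.  The curve is non-increasing in the threshold.
    """
    if corr.n_units < 2:
        raise ValueError("network degree needs at least 2 units")
    thresholds = DEGREE_THRESHOLDS if thresholds is None else np.asarray(thresholds, float)
    tri = corr.offdiag()
    percent = np.array([100.0 * np.count_nonzero(tri > t) / tri.size for t in thresholds])
    return thresholds, percent


def connectivity(corr: CorrelationMatrix, threshold: float) -> np.ndarray:
    """Per-unit percentage of partners correlated strictly above ``threshold``."""
    n = corr.n_units
    if n < 2:
        raise ValueError("connectivity needs at least 2 units")
    above = corr.values > threshold
    np.fill_diagonal(above, False)
    return 100.0 * above.sum(axis=1) / (n - 1)


def cluster(corr: CorrelationMatrix, percentile: float = 80.0) -> np.ndarray:
    """Group units whose connections are stronger than ``percentile`` % of
    all off-diagonal values; clusters are the connected components of the
    resulting graph (singletons allowed).  Returns a cluster id per unit."""
    n = corr.n_units
    if n < 2:
        raise ValueError("clustering needs at least 2 units")
    iu = np.triu_indices(n, k=1)
    cut = np.percentile(corr.values[iu], percentile)
    adj = np.zeros((n, n), dtype=bool)
    adj[iu] = corr.values[iu] > cut
    adj |= adj.T
    _, labels = connected_components(csr_matrix(adj), directed=False)
    return labels


def _discretize(series: np.ndarray, n_bins: int) -> np.ndarray:
    """Binary series pass through; continuous series get quantile bins."""
    x = np.asarray(series)
    uniq = np.unique(x)
    if len(uniq) <= 2 and np.isin(uniq, (0, 1)).all():
        return x.astype(np.int64)
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right").astype(np.int64)


def _entropy_bits(codes: np.ndarray) -> float:
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _joint(*arrays: np.ndarray) -> np.ndarray:
    code = np.zeros_like(arrays[0])
    for a in arrays:
        code = code * (a.max() + 1) + a
    return code


def transfer_entropy(
    source: np.ndarray, receiver: np.ndarray, L: int = 1, n_bins: int = 3
) -> float:
    """Plug-in transfer entropy (bits) from ``source`` to ``receiver``.

    Estimates ``H(Y_t | Y-past) - H(Y_t | Y-past, X-past)`` with history
    length ``L`` using maximum-likelihood histogram entropies; continuous
    inputs are quantile-binned into ``n_bins`` symbols, binary inputs used
    as-is.  Clamped at 0 (the plug-in difference can go slightly negative).
    """
    x = np.asarray(source)
    y = np.asarray(receiver)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("source and receiver must be equal-length 1-D series")
    if L < 1:
        raise ValueError("history length L must be >= 1")
    n = len(x)
    if n < L + 2:
        raise ValueError(f"series of length {n} too short for L = {L}")
    xs = _discretize(x, n_bins)
    ys = _discretize(y, n_bins)
    yt = ys[L:]
    ypast = _joint(*[ys[L - k : n - k] for k in range(1, L + 1)])
    xpast = _joint(*[xs[L - k : n - k] for k in range(1, L + 1)])
    te = (
        _entropy_bits(_joint(yt, ypast))
        + _entropy_bits(_joint(ypast, xpast))
        - _entropy_bits(ypast)
        - _entropy_bits(_joint(yt, ypast, xpast))
    )
    return max(te, 0.0)


def transfer_entropy_matrix(
    data: np.ndarray, L: int = 1, n_bins: int = 3
) -> np.ndarray:
    """Directed TE for every ordered unit pair (row = source, column =
    receiver); the diagonal is set to 0."""
    data = np.asarray(data)
    n = data.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = transfer_entropy(data[i], data[j], L=L, n_bins=n_bins)
    return out


def correlation_summary(corr: CorrelationMatrix) -> dict[str, float]:
    """Mean, min, max and range of the off-diagonal upper-triangle values."""
    if corr.n_units < 2:
        raise ValueError("summary needs at least 2 units")
    tri = corr.offdiag()
    return {
        "mean": float(tri.mean()),
        "min": float(tri.min()),
        "max": float(tri.max()),
        "range": float(tri.max() - tri.min()),
    }
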