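"""Activity-shuffling surrogate null model.

A surrogate preserves, per neuron, the NUMBER of active states exactly,
while re-drawing their durations and positions: each active state's new
duration is drawn uniformly from {1, ..., 2d - 1} around its original
duration d (so the unit's total active time is conserved in expectation,
not exactly), and the states are then placed at uniformly random
non-overlapping, non-touching positions (uniform composition of the free
frames into the gaps).  This destroys pairwise timing relationships while
holding each unit's activation count fixed and its activity load fixed in
expectation.

Comparing metrics between original and surrogate data shows which network
statistics reflect genuine co-ordination rather than marginal activity
levels.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .core import ActivityMask, Interval, MetricConfig, Recording, ShuffleConfig
from .correlation import correlation_summary, pearson_matrix
from .metrics import network_spike_peak, network_spike_rate

__all__ = ["shuffle_unit", "shuffle_network", "compare_metrics"]


def _random_composition(total: int, parts: int, rng: np.random.Generator, min_part: int) -> np.ndarray:
    """Uniform random composition of ``total`` into ``parts`` integers each
    >= ``min_part`` (stars-and-bars sampling)."""
    if parts == 0:
        return np.zeros(0, dtype=int)
    free = total - parts * min_part
    if free < 0:
        raise ValueError("infeasible composition")
    # choose parts-1 cut positions among free + parts - 1 slots
    if parts == 1:
        return np.array([total])
    cuts = np.sort(rng.choice(free + parts - 1, size=parts - 1, replace=False))
    gaps = np.diff(np.concatenate(([-1], cuts, [free + parts - 1]))) - 1
    return gaps + min_part


def shuffle_unit(intervals: list[Interval], n_frames: int, rng: np.random.Generator) -> list[Interval]:
    """Surrogate interval list for one unit: same interval count, each
    duration re-drawn uniformly around its original value, placements
    uniform among non-overlapping, non-touching arrangements.

    Gaps between placed intervals are at least one frame, so the surrogate
    rasterizes back to exactly the same number of active states.
    """
    k = len(intervals)
    if k == 0:
        return []
    durs_orig = np.array([e - s for s, e in intervals], dtype=int)
    if durs_orig.sum() + (k - 1) > n_frames:
        raise ValueError("intervals exceed recording length")
    for _ in range(100):
        durations = np.array([rng.integers(1, 2 * d) for d in durs_orig])
        if durations.sum() + (k - 1) <= n_frames:
            break
    else:
        # pathologically dense activity: keep the original durations
        durations = durs_orig.copy()
    rng.shuffle(durations)
    free = n_frames - int(durations.sum()) - (k - 1)
    gaps = _random_composition(free, k + 1, rng, min_part=0)
    out: list[Interval] = []
    t = 0
    for i, d in enumerate(durations):
        t += int(gaps[i]) + (1 if i > 0 else 0)
        out.append((t, t + int(d)))
        t += int(d)
    return out


def shuffle_network(mask: ActivityMask, cfg: ShuffleConfig) -> list[ActivityMask]:
    """Generate ``cfg.num_of_shuffles`` independent surrogates.

    In each iteration ``ceil(ratio * n_units)`` units (re-drawn uniformly
    every iteration) are shuffled; the rest are copied untouched.  Fully
    reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_units = mask.n_units
    n_shuffled = math.ceil(cfg.ratio * n_units)
    surrogates = []
    for _ in range(cfg.num_of_shuffles):
        chosen = rng.choice(n_units, size=n_shuffled, replace=False) if n_shuffled else np.array([], dtype=int)
        chosen_set = set(chosen.tolist())
        ivs = [
            shuffle_unit(mask.intervals[u], mask.n_frames, rng) if u in chosen_set else list(mask.intervals[u])
            for u in range(n_units)
        ]
        surrogates.append(
            ActivityMask.from_intervals(ivs, mask.n_frames, unit_ids=mask.unit_ids.copy())
        )
    return surrogates


def compare_metrics(
    original: ActivityMask,
    surrogates: list[ActivityMask],
    rec: Recording | None = None,
    corr_method: str = "active",
    metric_cfg: MetricConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Metric table for the original mask and every surrogate.

    Columns: mean Pearson correlation (``corr_method``), correlation range,
    mean network spike rate and mean network spike peak.  The second return
    value summarizes the surrogate rows as mean ± SEM per column.
    """
    if not surrogates:
        raise ValueError("need at least one surrogate")
    metric_cfg = metric_cfg or MetricConfig()
    fps = rec.fps if rec is not None else 20.0

    def row(label: str, m: ActivityMask) -> dict:
        corr = pearson_matrix(rec, m, method=corr_method)
        summ = correlation_summary(corr)
        return {
            "label": label,
            "mean_correlation": summ["mean"],
            "correlation_range": summ["range"],
            "mean_nsr": float(np.mean(network_spike_rate(m, metric_cfg, fps))),
            "mean_nsp": float(np.mean(network_spike_peak(m, metric_cfg, fps))),
        }

    rows = [row("original", original)]
    rows += [row(f"shuffle_{i + 1}", s) for i, s in enumerate(surrogates)]
    table = pd.DataFrame(rows)

    surr = table.iloc[1:].drop(columns="label")
    sem = surr.std(ddof=1) / np.sqrt(len(surr)) if len(surr) > 1 else surr.iloc[0] * 0.0
    summary = pd.DataFrame({"mean": surr.mean(), "sem": sem})
    return table, summary
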