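# Methods

This note documents the models and numerical choices behind caminet, the
parameters that matter, what the synthetic generator does and does not
emulate, and the known limitations.

## Active-state segmentation

A calcium transient is detected from the *rate of rise* of the denoised
fluorescence trace.  Per neuron: centered moving-average smoothing
(window `wnd_size` frames), discrete derivative `x′_t = x_t − x_{t−1}`
(element 0 defined as 0 so lengths stay aligned), adaptive threshold
`median(x′) + mad(x′)` where `mad` is the **mean** absolute deviation
about the median — the median pairs naturally with a median-anchored
deviation, and the pair tracks each neuron's own noise floor without any
global tuning.  Threshold crossing is strict (`>`), so a perfectly flat
trace yields no activity.

Edge handling: the smoothing window is truncated at the series ends and
renormalized by the number of samples actually covered, which preserves
constants and the series length.  The effective centered window spans
`t − ⌊wnd_size/2⌋ … t + ⌊wnd_size/2⌋`; `wnd_size = 1` is the identity.

*Spike* mode keeps the supra-threshold rise frames.  *Full* mode extends
each spike interval forward through the decay until the smoothed
intensity falls back to its value at the interval's onset, capped at the
next interval's onset — an onset-level termination rule chosen because
the decay has no other natural endpoint on a drifting baseline.  Spike
frames are a subset of full frames for every input.

Refinement order is warm-merge **then** cold-drop: merging first lets
genuine bursts separated by tiny gaps survive a subsequent duration cut.
Consequence worth knowing: with `cold > 0`, increasing `warm` can
*increase* the interval count (a merged interval survives a drop its
fragments would not); the count-monotonicity of `warm` holds at
`cold = 0`.

Defaults `wnd_size = 10`, `warm = 15`, `cold = 0`, spike mode, at 20 fps.
Intervals are half-open `[start, end)` 0-based frame indices everywhere.

## Activity metrics

Burst rate is reported per neuron in activations/min (interval count over
duration).  NSR/NSP tile the recording into consecutive non-overlapping
windows of `interval_s` seconds (default 3 s; meaningful range roughly
1–60 s); a trailing partial window is kept iff it covers at least half a
window.  NSR counts a unit as active in a window if it is active at ≥ 1
frame (union semantics), hence NSR ≥ NSP window-wise.  NSD uses a strict
`>` against `nsd_threshold` (default 0.1, i.e. 10% of units
simultaneously active).  All three are invariant under unit relabeling.

## Pairwise co-activity

Pearson's r is computed on the representation the mode names: raw traces,
frame-to-frame derivatives, or binary active series.  `active_acc` is the
literal ratio of simultaneous activity to the *sum* of individual
activities, so its ceiling is 0.5 (identical masks) — it is deliberately
the strictest mode.  Zero-variance series yield `r = 0` with a warning
rather than NaN, keeping downstream thresholding total; Pearson
diagonals are fixed at 1.

Lag semantics: the reported r is the maximum plain Pearson over integer
shifts `s ∈ [−lag, +lag]` with truncated overlap.  `lag = 0` reduces
exactly to the unshifted estimator.  Maximization is the permissive
reading of "co-active within a delay" and is symmetric in the pair.

Network degree counts unordered pairs with `r > t` (strict) on the grid
`t = 0, 0.05, …, 1`; it is non-increasing and reaches 0 at `t = 1`.  The
mean of per-unit connectivity shares equals the degree value at the same
threshold exactly (each pair is counted twice under both normalizations).
Clustering draws an edge where r strictly exceeds the 80th percentile of
the off-diagonal values and reports connected components; note the rule
degenerates to all-singletons when > 20% of pairs share the top value.

Transfer entropy uses plug-in (maximum-likelihood) histogram entropies in
bits with history length `L` (default 1); continuous inputs are
quantile-binned (default 3 bins), binary inputs used as-is, and the
estimate is clamped at 0.  No bias correction is applied: at the series
lengths used here (thousands of frames) the plug-in bias for binary
inputs is ≲ 0.001 bits, verified against the analytic 1-bit deterministic
coupling and the 0-bit independent pair.

## Distance analysis

The center of mass is the unweighted mean of unit centroids, per
recording; `rho` is each unit's distance to it.  Pair distances are
Euclidean (straight-line pixels) or radial (`|rho_i − rho_j|`, never
exceeding the Euclidean).  The distance factor `k = d/(d + d0)` maps
distances into [0, 1); `d0` defaults to the 25th percentile of the
recording's own Euclidean pair distances, which adapts to the field of
view (a fixed `d0 = 100` px can be passed for strict reproduction of
analyses that used that constant).  The optional distance-weighted
correlation is the product `r × k` exposed as an extra column, never
overwriting raw r.

## Shuffling null

The defining constraint is exact conservation of each neuron's activation
count.  Durations are re-drawn per state as `DiscreteUniform{1, …, 2d−1}`
around the original duration `d` — the total active time is conserved in
expectation, not exactly — and states are placed uniformly among
non-overlapping arrangements with interior gaps ≥ 1 frame (touching
states would rasterize into one and silently break the count
constraint).  Placement uses stars-and-bars sampling, so all feasible
arrangements are equally likely.  Each iteration independently draws
`ceil(ratio × n_units)` units to shuffle; `ratio = 0` is the identity and
everything is reproducible from the seed.  Reported comparisons are
mean ± SEM over iterations; formal hypothesis testing is left to the
user's statistics software.

## PCA embedding

Feature columns are z-scored before the SVD — the metrics mix percent,
per-minute rates and pixels, and unscaled PCA would be dominated by pixel
distances; standardization is a config-level choice with default on.
Constant columns are dropped with a warning.  The embedding is
scikit-learn's SVD-based PCA with a deterministic sign convention (each
component's largest-magnitude loading is positive).  Degenerate inputs
fail loudly: fewer than two recordings, fewer than two varying features,
or zero total variance.  Feature ranking uses |loading| on a chosen
component, or — when a "state" label set is supplied — the 2-D loading
norm, with cosine similarity between each feature's loading vector and
the difference of group centroids in the embedding plane.

## Synthetic generator

The generator emulates the *output of a CNMF pipeline*, not raw video:
per neuron a homogeneous-Poisson train (default 2 events/min) of
GCaMP6s-like kernels (linear rise over 5 frames, exponential decay with
τ = 40 frames at 20 fps), truncated-normal amplitudes (1.0 ± 0.2), plus
baseline noise of sd 0.1 (signal-to-noise 10).  The noise is a
low-frequency Gaussian process — white noise filtered with a Gaussian
kernel of width `noise_timescale_frames` (default 100 frames ≈ 5 s),
rescaled to `noise_sd` — because CNMF-denoised traces carry slow baseline
wobble rather than frame-rate shot noise.  This matters: the median+MAD
threshold sits at ~0.8 MAD above the median of the derivative
distribution, so any *broadband* noise that dominates that distribution
puts 5–20% of frames above threshold regardless of its amplitude and
floods the segmentation with false states.  On slow noise the derivative
is small relative to event rises and recovery at SNR 10 is
recall ≈ 1.00 / precision ≈ 0.99.  Setting `noise_timescale_frames = 0`
gives white noise for stress-testing; a linear drift term is available
via `drift_per_minute`.

Correlated groups share a Poisson onset template up to ± jitter (default
2 frames); group members are the first `n_groups × group_size` units.
Positions are uniform in a square arena (default 300 px).  Everything is
bit-reproducible from the seed.

What the generator does **not** emulate: photobleaching curves, motion
artifacts, overlapping-footprint crosstalk, bursty (non-Poisson) firing,
amplitude–duration correlation, and inhibition.  Passing recovery tests
on these fixtures therefore shows correctness of the *rules*, not
field-readiness for every recording quality.

Detection scoring: a planted event counts as recovered when a detected
interval overlaps its rise window widened by 7 frames (the 10-frame
smoothing window shifts edges by up to ~half its width plus the
derivative lag); a detected interval is a true positive when it overlaps
at least one such window.

## Problem sizes

Tests and the acceptance script run on 100-unit, 5-minute recordings for
detection recovery and 30–60-unit recordings for network-level checks —
sizes chosen to match a typical single-session miniscope field of view
while keeping every check well inside interactive runtimes.

## Known limitations

- Full-mode termination (return to onset intensity) is one of several
  defensible readings of "decline"; on strongly drifting baselines it can
  extend states to the next onset.
- The plug-in TE estimator is biased upward for short series or many
  bins; use L = 1 and few bins unless frames are plentiful.
- `active_acc` ignores lag-induced near-misses unless a lag is given.
- The shuffling null preserves counts but not durations exactly; metrics
  sensitive to total active time (e.g. NSD at low thresholds) can shift
  slightly between original and surrogates for that reason alone.
- Distances are in pixels; no micrometer calibration is attempted.
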