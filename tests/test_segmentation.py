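import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from caminet import SegmentationParams, segment_recording
from caminet.segmentation import adaptive_threshold, derivative, refine, segment, smooth


def oracle_segment(trace, wnd, warm, cold, mode="spike"):
    """Independent straight-line re-implementation of the segmentation rules,
    used only as a reference in tests."""
    n = len(trace)
    half = wnd // 2
    sm = np.empty(n)
    for t in range(n):
        lo, hi = max(0, t - half), min(n, t + half + 1)
        sm[t] = np.mean(trace[lo:hi])
    d = np.zeros(n)
    for t in range(1, n):
        d[t] = sm[t] - sm[t - 1]
    med = np.median(d)
    thr = med + np.mean(np.abs(d - med))
    act = d > thr
    ivs, t = [], 0
    while t < n:
        if act[t]:
            s = t
            while t < n and act[t]:
                t += 1
            ivs.append([s, t])
        else:
            t += 1
    if mode == "full":
        ext = []
        for i, (s, e) in enumerate(ivs):
            cap = ivs[i + 1][0] if i + 1 < len(ivs) else n
            t2 = e
            while t2 < cap and sm[t2] > sm[s]:
                t2 += 1
            ext.append([s, t2])
        ivs = []
        for s, e in ext:
            if ivs and s <= ivs[-1][1]:
                ivs[-1][1] = max(ivs[-1][1], e)
            else:
                ivs.append([s, e])
    merged = []
    for s, e in ivs:
        if merged and s - merged[-1][1] < warm:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if e - s >= max(cold, 1)]


class TestSmooth:
    def test_window_one_is_identity(self, rng):
        x = rng.normal(size=50)
        assert np.array_equal(smooth(x, 1), x)

    def test_edge_truncated_average(self):
        assert np.allclose(smooth(np.array([0.0, 0, 3, 0, 0]), 3), [0, 1, 1, 1, 0])

    def test_constant_preserved(self):
        assert np.allclose(smooth(np.full(30, 2.5), 10), 2.5)

    def test_rejects_bad_window(self):
        with pytest.raises(ValueError):
            smooth(np.zeros(5), 0)


class TestDerivative:
    def test_pairwise_differences_with_leading_zero(self):
        assert derivative(np.array([1.0, 3, 2])).tolist() == [0.0, 2.0, -1.0]

    def test_inverse_of_cumsum(self, rng):
        v = rng.normal(size=100)
        assert np.allclose(derivative(np.cumsum(v))[1:], v[1:], atol=1e-12)

    def test_too_short(self):
        with pytest.raises(ValueError):
            derivative(np.array([1.0]))


class TestAdaptiveThreshold:
    def test_hand_computed(self):
        # median 0, mean |deviation| = (0+0+10+0+0)/5 = 2
        assert adaptive_threshold(np.array([0.0, 0, 10, 0, 0])) == 2.0

    def test_zero_for_flat(self):
        assert adaptive_threshold(np.zeros(10)) == 0.0

    def test_translation_equivariance(self, rng):
        d = rng.normal(size=200)
        assert np.isclose(adaptive_threshold(d + 3.7), adaptive_threshold(d) + 3.7)


class TestRefine:
    @pytest.mark.parametrize(
        "intervals, warm, cold, expected",
        [
            ([(10, 20), (24, 30)], 10, 0, [(10, 30)]),  # gap 4 < 10: merge
            ([(10, 15)], 0, 8, []),  # length 5 < 8: drop
            ([(10, 20), (24, 30)], 0, 0, [(10, 20), (24, 30)]),  # defaults off
            ([(0, 2), (5, 6), (9, 20)], 4, 3, [(0, 20)]),  # merge first, then keep
        ],
    )
    def test_stated_rules(self, intervals, warm, cold, expected):
        assert refine(intervals, warm, cold) == expected


class TestSegment:
    def test_flat_trace_has_no_activity(self):
        ivs, binary = segment(np.zeros(100))
        assert ivs == [] and not binary.any()

    def test_noiseless_transient_spike_and_full(self):
        # linear rise frames 50-60, exponential decay back to baseline
        tr = np.zeros(300)
        tr[50:60] = np.arange(1, 11) / 10.0
        tr[60:] = np.exp(-np.arange(240) / 20.0)
        ivs, _ = segment(tr, SegmentationParams(warm=0))
        assert len(ivs) == 1
        s, e = ivs[0]
        assert s >= 45 and e <= 65
        assert s <= 50 + 5 and e >= 55  # covers the steep rise
        full_ivs, full_bin = segment(tr, SegmentationParams(warm=0, mode="full"))
        _, spike_bin = segment(tr, SegmentationParams(warm=0))
        assert full_ivs[0][1] > e  # decay frames included
        assert not (spike_bin & ~full_bin).any()

    def test_spike_frames_subset_of_full_frames(self, rng):
        for _ in range(100):
            tr = np.cumsum(rng.normal(size=150)) + rng.normal(0, 0.2, 150)
            _, spike = segment(tr, SegmentationParams(warm=5))
            _, full = segment(tr, SegmentationParams(warm=5, mode="full"))
            assert not (spike & ~full).any()

    def test_matches_independent_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(20, 200))
            tr = rng.normal(size=n).cumsum()
            wnd = int(rng.integers(1, 15))
            warm = int(rng.integers(0, 20))
            cold = int(rng.integers(0, 5))
            mode = rng.choice(["spike", "full"])
            ivs, _ = segment(tr, SegmentationParams(wnd_size=wnd, warm=warm, cold=cold, mode=mode))
            assert ivs == oracle_segment(tr, wnd, warm, cold, mode)

    @given(st.integers(0, 30), st.integers(0, 30))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_warm_cold_monotonicity(self, warm, cold):
        # warm monotonicity holds with cold disabled (a longer merged
        # interval can otherwise survive a cold drop and raise the count)
        rng = np.random.default_rng(99)
        tr = rng.normal(size=300).cumsum()
        base0, _ = segment(tr, SegmentationParams(warm=warm, cold=0))
        more_warm, _ = segment(tr, SegmentationParams(warm=warm + 5, cold=0))
        assert len(more_warm) <= len(base0)
        base, _ = segment(tr, SegmentationParams(warm=warm, cold=cold))
        more_cold, _ = segment(tr, SegmentationParams(warm=warm, cold=cold + 5))
        assert sum(e - s for s, e in more_cold) <= sum(e - s for s, e in base)


class TestSegmentRecording:
    def test_deterministic_and_consistent(self, small_recording):
        rec, _ = small_recording
        m1 = segment_recording(rec)
        m2 = segment_recording(rec)
        assert np.array_equal(m1.active, m2.active)
        for u in range(m1.n_units):
            rebuilt = np.zeros(m1.n_frames, dtype=bool)
            for s, e in m1.intervals[u]:
                rebuilt[s:e] = True
            assert np.array_equal(rebuilt, m1.active[u])

    def test_flat_recording_all_inactive(self):
        from caminet import Recording, TraceMatrix

        rec = Recording(traces=TraceMatrix(intensities=np.zeros((3, 50)), fps=20))
        mask = segment_recording(rec)
        assert not mask.active.any()
        assert all(ivs == [] for ivs in mask.intervals)
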