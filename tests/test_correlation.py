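import numpy as np
import pytest

from caminet import (
    ActivityMask,
    CorrelationMatrix,
    Recording,
    TraceMatrix,
    active_acc,
    cluster,
    connectivity,
    correlation_summary,
    network_degree,
    pearson_matrix,
    transfer_entropy,
    transfer_entropy_matrix,
)


def textbook_pearson(x, y):
    mx, my = np.mean(x), np.mean(y)
    num = np.sum((x - mx) * (y - my))
    den = np.sqrt(np.sum((x - mx) ** 2) * np.sum((y - my) ** 2))
    return num / den


def rec_from(data, fps=20.0):
    return Recording(traces=TraceMatrix(intensities=np.asarray(data, float), fps=fps))


class TestPearsonMatrix:
    def test_identical_and_negated_traces(self, rng):
        x = rng.normal(size=200)
        corr = pearson_matrix(rec_from([x, x, -x]), None, method="signal")
        assert corr.values[0, 1] == pytest.approx(1.0)
        assert corr.values[0, 2] == pytest.approx(-1.0)
        assert np.array_equal(corr.values, corr.values.T)
        assert np.allclose(np.diag(corr.values), 1.0)

    def test_matches_textbook_formula(self, rng):
        data = rng.normal(size=(6, 100))
        corr = pearson_matrix(rec_from(data), None, method="signal")
        for i in range(6):
            for j in range(i + 1, 6):
                assert corr.values[i, j] == pytest.approx(
                    textbook_pearson(data[i], data[j]), abs=1e-12
                )

    def test_diff_method_correlates_derivatives(self, rng):
        x = rng.normal(size=300).cumsum()
        y = x + 5.0
        corr = pearson_matrix(rec_from([x, y]), None, method="diff")
        assert corr.values[0, 1] == pytest.approx(1.0)

    def test_shifted_copy_recovered_at_lag(self, rng):
        x = rng.normal(size=500)
        y = np.roll(x, 2)
        corr0 = pearson_matrix(rec_from([x, y]), None, method="signal", lag=0)
        corr2 = pearson_matrix(rec_from([x, y]), None, method="signal", lag=2)
        assert corr0.values[0, 1] < 0.99
        assert corr2.values[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_lag_zero_equals_plain(self, rng):
        data = rng.normal(size=(4, 200))
        a = pearson_matrix(rec_from(data), None, method="signal", lag=0)
        b = pearson_matrix(rec_from(data), None, method="signal")
        assert np.array_equal(a.values, b.values)

    def test_zero_variance_guarded(self):
        data = np.vstack([np.zeros(50), np.arange(50.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = pearson_matrix(rec_from(data), None, method="signal")
        assert corr.values[0, 1] == 0.0

    def test_binary_methods_use_mask(self, rng):
        active = rng.random((3, 400)) < 0.3
        mask = ActivityMask.from_binary(active)
        corr = pearson_matrix(None, mask, method="active")
        expect = textbook_pearson(active[0].astype(float), active[1].astype(float))
        assert corr.values[0, 1] == pytest.approx(expect, abs=1e-12)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            pearson_matrix(rec_from(np.zeros((2, 10))), None, method="bogus")


class TestActiveAcc:
    def test_identical_masks_reach_half(self):
        m = np.zeros(100, bool)
        m[:40] = True
        assert active_acc(m, m) == 0.5

    def test_disjoint_masks_zero(self):
        a = np.zeros(100, bool)
        b = np.zeros(100, bool)
        a[:30] = True
        b[50:80] = True
        assert active_acc(a, b) == 0.0

    def test_empty_masks_guarded(self):
        z = np.zeros(50, bool)
        assert active_acc(z, z) == 0.0

    def test_matrix_symmetric_with_half_diagonal(self, rng):
        active = rng.random((4, 300)) < 0.25
        mask = ActivityMask.from_binary(active)
        corr = pearson_matrix(None, mask, method="active_acc")
        assert np.array_equal(corr.values, corr.values.T)
        assert np.allclose(np.diag(corr.values)[active.any(axis=1)], 0.5)
        assert (corr.values <= 0.5 + 1e-12).all() and (corr.values >= 0).all()


class TestNetworkDegree:
    def test_extreme_matrices(self):
        ones = np.ones((5, 5))
        thr, pct = network_degree(CorrelationMatrix(values=ones, method="signal"))
        assert (pct[thr < 1.0] == 100.0).all() and pct[-1] == 0.0
        zeros = np.eye(5)
        _, pct0 = network_degree(CorrelationMatrix(values=zeros, method="signal"))
        assert (pct0 == 0.0).all()

    def test_brute_force_and_monotone(self, rng):
        vals = rng.uniform(-1, 1, size=(8, 8))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        corr = CorrelationMatrix(values=vals, method="signal")
        thr, pct = network_degree(corr)
        pairs = [(i, j) for i in range(8) for j in range(i + 1, 8)]
        for t, p in zip(thr, pct):
            brute = 100.0 * sum(vals[i, j] > t for i, j in pairs) / len(pairs)
            assert p == pytest.approx(brute, abs=1e-12)
        assert all(a >= b for a, b in zip(pct, pct[1:]))


class TestConnectivity:
    def test_share_of_partners(self):
        vals = np.eye(10)
        vals[0, 1:4] = vals[1:4, 0] = 0.9
        corr = CorrelationMatrix(values=vals, method="signal")
        conn = connectivity(corr, threshold=0.5)
        assert conn[0] == pytest.approx(100.0 * 3 / 9)

    def test_mean_connectivity_equals_degree(self, rng):
        vals = rng.uniform(-1, 1, size=(9, 9))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        corr = CorrelationMatrix(values=vals, method="signal")
        thr, pct = network_degree(corr)
        for t, p in zip(thr, pct):
            assert np.mean(connectivity(corr, t)) == pytest.approx(p, abs=1e-12)


class TestCluster:
    def test_two_blocks_separate(self, rng):
        # two 3-unit blocks among 10 units: within-block pairs are the only
        # values above the 80th percentile of the (mostly zero) off-diagonal
        n = 10
        vals = np.eye(n)
        for block in ([0, 1, 2], [3, 4, 5]):
            for i in block:
                for j in block:
                    if i != j:
                        vals[i, j] = 0.9
        corr = CorrelationMatrix(values=vals, method="active")
        labels = cluster(corr)
        multi = [c for c in np.unique(labels) if (labels == c).sum() > 1]
        assert len(multi) == 2
        assert len(set(labels[:3])) == 1 and len(set(labels[3:6])) == 1
        assert labels[0] != labels[3]

    def test_all_equal_offdiagonal_gives_singletons(self):
        vals = np.full((6, 6), 0.4)
        np.fill_diagonal(vals, 1.0)
        labels = cluster(CorrelationMatrix(values=vals, method="active"))
        assert len(np.unique(labels)) == 6

    def test_permutation_equivariance(self, rng):
        vals = rng.uniform(0, 1, size=(7, 7))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        labels = cluster(CorrelationMatrix(values=vals, method="active"))
        perm = rng.permutation(7)
        labels_p = cluster(CorrelationMatrix(values=vals[np.ix_(perm, perm)], method="active"))
        # same partition up to relabeling
        for i in range(7):
            for j in range(7):
                assert (labels[perm[i]] == labels[perm[j]]) == (labels_p[i] == labels_p[j])


class TestTransferEntropy:
    def test_constant_receiver_is_zero(self, rng):
        x = rng.integers(0, 2, 500)
        assert transfer_entropy(x, np.zeros(500), L=1) == 0.0

    def test_deterministic_coupling_one_bit(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 2, 5000)
        y = np.empty(5000, dtype=int)
        y[0] = 0
        y[1:] = x[:-1]
        assert transfer_entropy(x, y, L=1) == pytest.approx(1.0, abs=0.02)

    def test_independent_pair_near_zero(self):
        vals = [
            transfer_entropy(
                np.random.default_rng(100 + s).integers(0, 2, 5000),
                np.random.default_rng(900 + s).integers(0, 2, 5000),
                L=1,
            )
            for s in range(20)
        ]
        assert np.mean(vals) <= 0.01

    def test_self_te_zero_and_nonnegative(self, rng):
        x = rng.integers(0, 2, 1000)
        assert transfer_entropy(x, x.copy(), L=1) == 0.0
        cont = rng.normal(size=(3, 400))
        te = transfer_entropy_matrix(cont, L=1, n_bins=3)
        assert (te >= 0).all() and np.allclose(np.diag(te), 0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            transfer_entropy(np.zeros(3), np.zeros(3), L=2)


class TestSummary:
    def test_statistics_over_triangle(self):
        vals = np.eye(3)
        vals[0, 1] = vals[1, 0] = 0.1
        vals[0, 2] = vals[2, 0] = 0.9
        vals[1, 2] = vals[2, 1] = 0.5
        s = correlation_summary(CorrelationMatrix(values=vals, method="signal"))
        assert s["range"] == pytest.approx(0.8)
        assert s["mean"] == pytest.approx(0.5)
        assert s["min"] == 0.1 and s["max"] == 0.9
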