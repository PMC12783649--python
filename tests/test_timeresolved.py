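"""Sliding-window MI and time-resolved weighted-degree traces."""
import numpy as np
import pytest

from tracnet.network import UniversalGraph
from tracnet.contacts import FingerprintMatrix
from tracnet.timeresolved import (
    WindowGrid,
    optimize_window,
    trac_traces,
    windowed_mi,
)
from conftest import mi_2x2_oracle


def oracle_windowed_mi(x, y, t, delta):
    xw = np.asarray(x)[t - delta : t + delta]
    yw = np.asarray(y)[t - delta : t + delta]
    n11 = int(np.sum((xw == 1) & (yw == 1)))
    n10 = int(np.sum((xw == 1) & (yw == 0)))
    n01 = int(np.sum((xw == 0) & (yw == 1)))
    n00 = int(np.sum((xw == 0) & (yw == 0)))
    return mi_2x2_oracle(n11, n10, n01, n00)


class TestWindowGrid:
    def test_defaults(self):
        grid = WindowGrid()
        assert grid.sizes == (150, 300, 450, 600, 750, 900, 1050)
        assert grid.half_widths == (75, 150, 225, 300, 375, 450, 525)

    def test_odd_size_rejected(self):
        with pytest.raises(ValueError, match="even"):
            WindowGrid((151,))

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            WindowGrid((300, 150))

    def test_evaluation_times_fit_smallest_window(self):
        grid = WindowGrid((150, 300), stride=10)
        times = grid.evaluation_times(1000)
        assert times[0] == 75 and times[-1] <= 925


class TestWindowedMI:
    def test_identical_balanced_window_is_one_bit(self):
        x = np.r_[np.ones(100, dtype=int), np.zeros(100, dtype=int)]
        assert windowed_mi(x, x, t=100, half_width=75) == pytest.approx(1.0, abs=1e-12)

    def test_constant_window_is_zero(self):
        x = np.ones(400, dtype=int)
        y = np.random.default_rng(0).integers(0, 2, 400)
        assert windowed_mi(x, y, 200, 100) == 0.0

    def test_out_of_bounds_window(self):
        x = np.zeros(100, dtype=int)
        with pytest.raises(ValueError, match="bounds"):
            windowed_mi(x, x, t=10, half_width=20)

    def test_matches_oracle_over_many_windows(self):
        rng = np.random.default_rng(42)
        x = rng.integers(0, 2, 5000)
        y = (x ^ (rng.random(5000) < 0.3)).astype(int)
        for t in rng.integers(100, 4900, 200):
            got = windowed_mi(x, y, int(t), 75)
            assert got == pytest.approx(oracle_windowed_mi(x, y, int(t), 75), abs=1e-12)


class TestOptimizeWindow:
    def test_planted_block_selects_matching_window(self):
        # coupled only inside a 300-frame block centered at t
        rng = np.random.default_rng(5)
        n, t = 4000, 2000
        x = rng.integers(0, 2, n)
        y = rng.integers(0, 2, n)
        block = slice(t - 150, t + 150)
        y[block] = x[block]
        grid = WindowGrid()
        size, mi = optimize_window(x, y, t, grid)
        explicit = {
            s: windowed_mi(x, y, t, s // 2) for s in grid.sizes
        }
        assert mi == max(explicit.values())
        assert explicit[size] == mi
        assert size <= 450  # a window close to the coupled block wins

    def test_tie_goes_to_largest_window(self):
        x = np.tile([1, 0], 2000)  # identical balanced streams everywhere
        size, mi = optimize_window(x, x, t=2000, grid=WindowGrid())
        assert (size, mi) == (1050, pytest.approx(1.0))

    def test_boundary_only_smallest_feasible(self):
        x = np.random.default_rng(0).integers(0, 2, 4000)
        size, _ = optimize_window(x, x, t=75, grid=WindowGrid())
        assert size == 150

    def test_no_feasible_window_is_sentinel(self):
        x = np.zeros(200, dtype=int)
        assert optimize_window(x, x, t=10, grid=WindowGrid((150,))) is None


class TestTracTraces:
    def test_additivity_identity(self, small_analysis):
        for traces in small_analysis["traces"].values():
            for tr in traces.values():
                if tr.edge_mi:
                    total = np.sum(list(tr.edge_mi.values()), axis=0)
                    assert np.array_equal(tr.values, total)

    def test_per_edge_bound_and_nonnegativity(self, small_analysis):
        for traces in small_analysis["traces"].values():
            for tr in traces.values():
                for mi in tr.edge_mi.values():
                    assert np.all(mi >= 0) and np.all(mi <= 1 + 1e-12)
                assert np.all(tr.values >= 0)
                assert np.all(tr.values <= len(tr.edge_mi) + 1e-9)

    def test_stride_invariance(self):
        rng = np.random.default_rng(9)
        n = 2000
        labels = ["A:A:1_A:A:10", "A:A:2_A:A:20"]
        X = rng.integers(0, 2, (n, 2))
        m = FingerprintMatrix(X, labels, "t")
        g = UniversalGraph(labels, {(labels[0], labels[1])})
        coarse = trac_traces(m, g, WindowGrid((150, 300), stride=20))[labels[0]]
        fine = trac_traces(m, g, WindowGrid((150, 300), stride=10))[labels[0]]
        shared = np.isin(fine.times, coarse.times)
        assert np.array_equal(fine.values[shared], coarse.values)

    def test_null_streams_stay_below_one_bit(self):
        # independent contacts: no window should show a strong dependency
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n, p = 6000, 10
            labels = [f"A:A:{i}_A:A:{i + 30}" for i in range(p)]
            m = FingerprintMatrix(rng.integers(0, 2, (n, p)), labels, "t")
            edges = {(labels[i], labels[i + 1]) for i in range(p - 1)}
            traces = trac_traces(m, UniversalGraph(labels, edges), WindowGrid(stride=50))
            if all(tr.max_amplitude < 1.0 for tr in traces.values()):
                hits += 1
        assert hits >= 4

    def test_shuffled_streams_collapse_peaks(self, small_ensemble):
        matrices, _, truth = small_ensemble
        m = matrices[0]
        members = truth.members(0)
        labels = members
        edges = {(labels[0], lab) for lab in labels[1:]}
        g = UniversalGraph(labels, edges)
        grid = WindowGrid(stride=25)
        real = trac_traces(m.restrict(labels), g, grid)[labels[0]].max_amplitude
        rng = np.random.default_rng(0)
        shuffled = m.restrict(labels).values.copy()
        rng.shuffle(shuffled)  # destroys temporal localization, keeps row structure
        perm = np.array([rng.permutation(shuffled[:, j]) for j in range(len(labels))]).T
        ms = FingerprintMatrix(perm, labels, "shuffled")
        null = trac_traces(ms, g, grid)[labels[0]].max_amplitude
        assert null < real / 2

    def test_miller_madow_shrinks_null_windows(self):
        # on independent streams the plug-in MI is biased upward; the
        # correction removes roughly 1/(2N ln 2) without going negative
        rng = np.random.default_rng(12)
        x = rng.integers(0, 2, 2000)
        y = rng.integers(0, 2, 2000)
        plain, corrected = [], []
        for t in range(200, 1800, 100):
            plain.append(windowed_mi(x, y, t, 75))
            corrected.append(windowed_mi(x, y, t, 75, bias_correction=True))
        assert all(c <= p for c, p in zip(corrected, plain))
        assert all(c >= 0 for c in corrected)
        assert np.mean(corrected) < np.mean(plain)

    def test_global_window_mode_uses_one_size_and_stays_additive(self):
        rng = np.random.default_rng(13)
        n = 3000
        labels = ["A:A:1_A:A:10", "A:A:2_A:A:20"]
        x = rng.integers(0, 2, n)
        y = (x ^ (rng.random(n) < 0.2)).astype(np.uint8)
        m = FingerprintMatrix(np.column_stack([x, y]), labels, "t")
        g = UniversalGraph(labels, {(labels[0], labels[1])})
        traces = trac_traces(m, g, WindowGrid(stride=20), window_mode="global")
        tr = traces[labels[0]]
        win = tr.edge_window[labels[1]]
        # one committed size away from the trajectory edges
        interior = (tr.times >= max(win) // 2) & (tr.times <= n - max(win) // 2)
        assert len(set(win[interior])) == 1
        assert not np.isnan(tr.edge_mi[labels[1]]).any()
        assert np.array_equal(tr.values, tr.edge_mi[labels[1]])

    def test_unknown_window_mode_rejected(self):
        labels = ["A:A:1_A:A:10", "A:A:2_A:A:20"]
        m = FingerprintMatrix(
            np.random.default_rng(0).integers(0, 2, (400, 2)), labels, "t"
        )
        g = UniversalGraph(labels, {(labels[0], labels[1])})
        with pytest.raises(ValueError, match="window_mode"):
            trac_traces(m, g, WindowGrid((150,), stride=50), window_mode="sometimes")

    def test_empty_neighborhood_flagged(self):
        labels = ["A:A:1_A:A:10", "A:A:2_A:A:20", "A:A:3_A:A:30"]
        m = FingerprintMatrix(
            np.random.default_rng(1).integers(0, 2, (400, 3)), labels, "t"
        )
        g = UniversalGraph(labels, {(labels[0], labels[1])})
        traces = trac_traces(m, g, WindowGrid((150,), stride=50))
        assert traces[labels[2]].empty_neighborhood
        assert np.all(traces[labels[2]].values == 0)

    def test_missing_column_treated_as_zero_with_warning(self):
        labels = ["A:A:1_A:A:10", "A:A:2_A:A:20"]
        m = FingerprintMatrix(
            np.random.default_rng(2).integers(0, 2, (400, 1)), labels[:1], "t"
        )
        g = UniversalGraph(labels, {(labels[0], labels[1])})
        with pytest.warns(UserWarning, match="missing"):
            traces = trac_traces(m, g, WindowGrid((150,), stride=50))
        assert np.all(traces[labels[0]].edge_mi[labels[1]] == 0)
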