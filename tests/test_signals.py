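"""Peak detection, ranking, key-TRAC selection, ordering, connectors."""
import numpy as np
import pytest

from tracnet.network import UniversalGraph
from tracnet.signals import (
    PeakSet,
    classify_order,
    find_connectors,
    find_peaks,
    rank_contacts,
    select_key_tracs,
)
from tracnet.timeresolved import TRACTrace


def make_trace(values, node="n", traj="t", stride=10):
    values = np.asarray(values, dtype=float)
    times = np.arange(values.size) * stride + 100
    tr = TRACTrace(node, times, {"edge": values}, {"edge": np.full(values.size, 150)}, traj)
    return tr


def bump(center, width, height, n=100):
    x = np.arange(n, dtype=float)
    return height * np.exp(-0.5 * ((x - center) / width) ** 2)


class TestFindPeaks:
    def test_single_bump_apex(self):
        tr = make_trace(bump(50, 5, 1.5))
        ps = find_peaks(tr, threshold=1.0, min_separation=50)
        assert ps.n_peaks == 1
        assert ps.peaks[0][0] == 100 + 50 * 10
        assert ps.peaks[0][1] == pytest.approx(1.5)

    def test_subthreshold_bump_ignored(self):
        ps = find_peaks(make_trace(bump(50, 5, 0.5)), threshold=1.0, min_separation=50)
        assert ps.n_peaks == 0

    def test_two_separated_bumps_ordered(self):
        tr = make_trace(bump(25, 4, 1.2) + bump(75, 4, 1.4))
        ps = find_peaks(tr, threshold=1.0, min_separation=100)
        assert ps.n_peaks == 2
        assert ps.peaks[0][0] < ps.peaks[1][0]

    def test_min_separation_keeps_higher(self):
        tr = make_trace(bump(40, 4, 1.2) + bump(60, 4, 1.6))
        ps = find_peaks(tr, threshold=1.0, min_separation=10 * 40)
        assert ps.n_peaks == 1
        assert ps.peaks[0][1] == pytest.approx(1.6, abs=0.05)

    def test_plateau_reports_center(self):
        values = np.zeros(101)
        values[40:61] = 2.0
        ps = find_peaks(make_trace(values), threshold=1.0, min_separation=10)
        assert ps.n_peaks == 1
        assert ps.peaks[0][0] == 100 + 50 * 10

    def test_threshold_monotonicity(self):
        tr = make_trace(bump(20, 3, 1.1) + bump(50, 3, 1.8) + bump(80, 3, 2.5))
        lower = {t for t, _ in find_peaks(tr, 1.0, 50).peaks}
        higher = {t for t, _ in find_peaks(tr, 2.0, 50).peaks}
        assert higher <= lower


def _ensemble(amplitudes: dict[str, list[float]]):
    """amplitudes[node] = per-trajectory max amplitude of a synthetic bump."""
    out = {}
    n_traj = len(next(iter(amplitudes.values())))
    for k in range(n_traj):
        out[f"t{k}"] = {
            node: make_trace(bump(50, 5, amps[k]), node=node, traj=f"t{k}")
            for node, amps in amplitudes.items()
        }
    return out


class TestRankContacts:
    def test_prevalence_dominates_amplitude(self):
        traces = _ensemble({"a": [1.1, 1.1, 1.1], "b": [9.0, 9.0, 0.2]})
        rm = rank_contacts(traces, threshold=1.0)
        assert rm.ranking[0] == "a"
        assert rm.n_above("a") == 3 and rm.n_above("b") == 2

    def test_mean_amplitude_breaks_prevalence_ties(self):
        traces = _ensemble({"a": [1.2, 1.2], "b": [1.8, 1.8]})
        rm = rank_contacts(traces, threshold=1.0)
        assert rm.ranking == ["b", "a"]

    def test_total_ranking_below_threshold(self):
        traces = _ensemble({"a": [0.2, 0.3], "b": [0.5, 0.6]})
        rm = rank_contacts(traces, threshold=1.0)
        assert rm.ranking == ["b", "a"]

    def test_overlay_consistent(self):
        traces = _ensemble({"a": [1.5, 0.5]})
        rm = rank_contacts(traces, threshold=1.0)
        assert rm.overlay.loc["a"].tolist() == [True, False]


def _peaksets(first_times: dict[str, dict[str, list[int]]], threshold=1.0):
    return {
        node: {
            traj: PeakSet(node, traj, [(t, 1.5) for t in times], threshold)
            for traj, times in per.items()
        }
        for node, per in first_times.items()
    }


class TestSelectKeyTracs:
    def test_all_criteria_met(self):
        traces = _ensemble({"a": [1.5, 1.5, 1.5], "b": [1.5, 1.5, 0.4]})
        rm = rank_contacts(traces, 1.0)
        peaks = _peaksets(
            {
                "a": {"t0": [200], "t1": [300], "t2": [250]},
                "b": {"t0": [200], "t1": [300], "t2": []},
            }
        )
        assert select_key_tracs(rm, peaks) == ["a"]

    def test_too_many_peaks_rejected(self):
        traces = _ensemble({"a": [1.5, 1.5]})
        rm = rank_contacts(traces, 1.0)
        peaks = _peaksets({"a": {"t0": [100, 200, 300], "t1": [100]}})
        with pytest.warns(UserWarning, match="no contact"):
            assert select_key_tracs(rm, peaks, max_peaks=2) == []

    def test_missing_trajectory_rejected_unless_relaxed(self):
        traces = _ensemble({"a": [1.5, 1.5, 0.2]})
        rm = rank_contacts(traces, 1.0)
        peaks = _peaksets({"a": {"t0": [100], "t1": [100], "t2": []}})
        with pytest.warns(UserWarning, match="no contact"):
            assert select_key_tracs(rm, peaks) == []
        assert select_key_tracs(rm, peaks, require_all_trajectories=False) == ["a"]


class TestClassifyOrder:
    def test_consistent_precedence(self):
        a = _peaksets({"a": {f"t{k}": [100] for k in range(5)}})["a"]
        b = _peaksets({"b": {f"t{k}": [200] for k in range(5)}})["b"]
        label, report = classify_order(a, b)
        assert label == "a_precedes_b"
        assert report["n_compared"] == 5

    def test_antisymmetry(self):
        a = _peaksets({"a": {"t0": [100], "t1": [150]}})["a"]
        b = _peaksets({"b": {"t0": [200], "t1": [250]}})["b"]
        assert classify_order(a, b)[0] == "a_precedes_b"
        assert classify_order(b, a)[0] == "b_precedes_a"

    def test_flip_in_one_trajectory_is_unordered(self):
        a = _peaksets({"a": {"t0": [100], "t1": [300]}})["a"]
        b = _peaksets({"b": {"t0": [200], "t1": [200]}})["b"]
        assert classify_order(a, b)[0] == "unordered"

    def test_simultaneous_first_peaks_unordered(self):
        a = _peaksets({"a": {"t0": [100]}})["a"]
        b = _peaksets({"b": {"t0": [100]}})["b"]
        assert classify_order(a, b)[0] == "unordered"

    def test_trajectories_without_peaks_excluded(self):
        a = _peaksets({"a": {"t0": [100], "t1": []}})["a"]
        b = _peaksets({"b": {"t0": [200], "t1": [50]}})["b"]
        label, report = classify_order(a, b)
        assert label == "a_precedes_b"
        assert report["n_excluded"] == 1

    def test_no_usable_trajectory_errors(self):
        a = _peaksets({"a": {"t0": []}})["a"]
        b = _peaksets({"b": {"t0": [100]}})["b"]
        with pytest.raises(ValueError, match="no shared"):
            classify_order(a, b)


class TestFindConnectors:
    def test_common_neighbor(self):
        g = UniversalGraph(["a", "b", "c"], {("a", "c"), ("b", "c")})
        assert find_connectors(g, "a", "b") == ["c"]

    def test_no_common_neighbor(self):
        g = UniversalGraph(["a", "b", "c", "d"], {("a", "c"), ("b", "d")})
        assert find_connectors(g, "a", "b") == []

    def test_hubs_excluded_even_if_adjacent(self):
        g = UniversalGraph(["a", "b", "c"], {("a", "b"), ("a", "c"), ("b", "c")})
        assert find_connectors(g, "a", "b") == ["c"]

    def test_unknown_hub(self):
        g = UniversalGraph(["a"], set())
        with pytest.raises(ValueError, match="hub"):
            find_connectors(g, "a", "zz")


class TestOnPlantedEnsemble:
    def test_enabler_precedes_effector(self, small_analysis):
        truth = small_analysis["truth"]
        traces = small_analysis["traces"]
        rm = rank_contacts(traces, threshold=1.0)
        enabler = next(n for n in rm.ranking if truth.community_of[n] == 0)
        effector = next(n for n in rm.ranking if truth.community_of[n] == 1)
        peaks_e = {t: find_peaks(traces[t][enabler], 1.0, 600) for t in traces}
        peaks_f = {t: find_peaks(traces[t][effector], 1.0, 600) for t in traces}
        label, _ = classify_order(peaks_e, peaks_f)
        assert label == "a_precedes_b"
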