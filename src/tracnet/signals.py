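"""Peak detection, ranking and ordering of TRAC signals.

A contact's D_i(t) trace shows peaks where its community's dependencies
manifest.  Across a trajectory ensemble, key TRACs are selected by three
criteria: amplitude above a bit threshold (default 1 bit), occurrence in
every trajectory, and at most a small number of peaks per trajectory
(macro-transitions, not microstate chatter).  The first-peak order between
two selected TRACs classifies them as enabler (always first) and effector
(always second); contacts adjacent to both hubs in the universal graph are
their connectors.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks as _scipy_find_peaks

from .network import UniversalGraph
from .timeresolved import TRACTrace

__all__ = [
    "PeakSet",
    "RankingMatrix",
    "find_peaks",
    "rank_contacts",
    "select_key_tracs",
    "classify_order",
    "find_connectors",
    "ensemble_std_threshold",
]

DEFAULT_PEAK_THRESHOLD_BITS = 1.0
EVOLUTION_HANDOFF_THRESHOLD_BITS = 2.0
DEFAULT_MAX_PEAKS = 2
#: default minimum peak separation: twice the largest grid window, so one
#: transition event is never counted as two peaks
DEFAULT_MIN_SEPARATION = 2 * 1050


@dataclass
class PeakSet:
    """Above-threshold local maxima of one node's trace in one trajectory."""

    node: str
    trajectory_id: str
    peaks: list[tuple[int, float]]  # (time, amplitude bits), times increasing
    threshold: float

    @property
    def first_peak_time(self) -> int | None:
        return self.peaks[0][0] if self.peaks else None

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


def find_peaks(
    trace: TRACTrace,
    threshold: float = DEFAULT_PEAK_THRESHOLD_BITS,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> PeakSet:
    """Local maxima of D_i(t) strictly above ``threshold``.

    ``min_separation`` is in frames; of two conflicting maxima the higher
    one is kept.  Plateau maxima report their center time.
    """
    values = trace.values
    times = trace.times
    if times.size >= 2:
        stride = int(times[1] - times[0])
        distance = max(1, int(np.ceil(min_separation / stride)))
    else:
        distance = 1
    idx, _ = _scipy_find_peaks(values, distance=distance, plateau_size=1)
    peaks = [
        (int(times[i]), float(values[i])) for i in idx if values[i] > threshold
    ]
    return PeakSet(trace.node, trace.trajectory_id, peaks, threshold)


@dataclass
class RankingMatrix:
    """Contacts x trajectories matrix of max D_i(t) amplitudes with the
    boolean above-threshold overlay and the derived ordering."""

    amplitudes: pd.DataFrame  # rows: contacts, columns: trajectory ids
    threshold: float
    ranking: list[str] = field(default_factory=list)

    @property
    def overlay(self) -> pd.DataFrame:
        return self.amplitudes > self.threshold

    def n_above(self, node: str) -> int:
        return int(self.overlay.loc[node].sum())


def rank_contacts(
    traces_by_trajectory: dict[str, dict[str, TRACTrace]],
    threshold: float = DEFAULT_PEAK_THRESHOLD_BITS,
) -> RankingMatrix:
    """Rank contacts by ensemble prevalence, then amplitude.

    Primary key: number of trajectories whose max amplitude exceeds the
    threshold (descending).  Secondary: mean max amplitude (descending).
    Final: label (ascending), for determinism.
    """
    traj_ids = list(traces_by_trajectory)
    if not traj_ids:
        raise ValueError("empty ensemble")
    nodes = sorted(next(iter(traces_by_trajectory.values())))
    for tid, traces in traces_by_trajectory.items():
        if sorted(traces) != nodes:
            raise ValueError(f"trajectory {tid!r} has a different node set")
    amp = pd.DataFrame(
        {
            tid: [traces_by_trajectory[tid][n].max_amplitude for n in nodes]
            for tid in traj_ids
        },
        index=nodes,
    )
    rm = RankingMatrix(amp, threshold)
    order = sorted(
        nodes,
        key=lambda n: (-rm.n_above(n), -float(amp.loc[n].mean()), n),
    )
    rm.ranking = order
    return rm


def select_key_tracs(
    ranking: RankingMatrix,
    peaksets: dict[str, dict[str, PeakSet]],
    amplitude_threshold: float = DEFAULT_PEAK_THRESHOLD_BITS,
    require_all_trajectories: bool = True,
    max_peaks: int = DEFAULT_MAX_PEAKS,
) -> list[str]:
    """Nodes meeting all three key-TRAC criteria.

    (1) max amplitude above ``amplitude_threshold`` in each trajectory
    considered, (2) present above threshold in *all* trajectories when
    ``require_all_trajectories``, (3) at most ``max_peaks`` peaks in any
    single trajectory.  Returned in ranking order.
    """
    import warnings

    n_traj = ranking.amplitudes.shape[1]
    selected = []
    for node in ranking.ranking:
        above = (ranking.amplitudes.loc[node] > amplitude_threshold).sum()
        if require_all_trajectories and above < n_traj:
            continue
        if above == 0:
            continue
        per_traj = peaksets.get(node, {})
        if any(ps.n_peaks > max_peaks for ps in per_traj.values()):
            continue
        selected.append(node)
    if not selected:
        warnings.warn("no contact satisfies all key-TRAC criteria", stacklevel=2)
    return selected


def classify_order(
    peaks_a: dict[str, PeakSet], peaks_b: dict[str, PeakSet]
) -> tuple[str, dict]:
    """Strict first-peak precedence of node a vs node b across trajectories.

    ``a_precedes_b`` iff in every trajectory where both nodes peak, the
    first peak of a is strictly earlier; symmetrically for b; otherwise
    ``unordered``.  Trajectories where either node has no peaks are
    excluded and counted in the report.
    """
    shared = sorted(set(peaks_a) & set(peaks_b))
    usable, excluded = [], []
    for tid in shared:
        if peaks_a[tid].n_peaks and peaks_b[tid].n_peaks:
            usable.append(tid)
        else:
            excluded.append(tid)
    if not usable:
        raise ValueError("no shared trajectory in which both nodes have peaks")
    a_first = sum(
        peaks_a[t].first_peak_time < peaks_b[t].first_peak_time for t in usable
    )
    b_first = sum(
        peaks_b[t].first_peak_time < peaks_a[t].first_peak_time for t in usable
    )
    if a_first == len(usable):
        label = "a_precedes_b"
    elif b_first == len(usable):
        label = "b_precedes_a"
    else:
        label = "unordered"
    report = {
        "n_compared": len(usable),
        "n_excluded": len(excluded),
        "excluded_trajectories": excluded,
        "a_first": a_first,
        "b_first": b_first,
    }
    return label, report


def find_connectors(graph: UniversalGraph, hub_a: str, hub_b: str) -> list[str]:
    """Contacts adjacent (direction ignored) to both hubs, hubs excluded."""
    for hub in (hub_a, hub_b):
        if hub not in graph.nodes:
            raise ValueError(f"hub {hub!r} not in graph")
    common = set(graph.neighbors(hub_a)) & set(graph.neighbors(hub_b))
    common -= {hub_a, hub_b}
    return sorted(common)


def ensemble_std_threshold(traces_by_trajectory: dict[str, dict[str, TRACTrace]]) -> float:
    """Data-driven alternative threshold: one standard deviation of all
    trace values pooled over the ensemble."""
    pool = np.concatenate(
        [tr.values for traces in traces_by_trajectory.values() for tr in traces.values()]
    )
    return float(pool.std())
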