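"""Time-resolved rescoring of the universal graph along one trajectory.

The static graph says *which* contact pairs are directly dependent; this
module says *when*.  For every edge (i, j) of the universal graph the
dependency strength is re-estimated inside a sliding window of half-width
delta centered at frame t:

    MI_t(i, j | delta) = H(x_i,w) + H(x_j,w) - H(x_i, x_j, w)

with the plug-in entropies (bits) of the two binary streams restricted to
the window w = [t - delta, t + delta).  The window size is optimized per
edge and per evaluation time by maximizing MI over a fixed grid of full
window lengths (defaults 150..1050 frames); ties resolve toward the
largest feasible window because small windows inflate the plug-in
estimate.

The time-resolved weighted degree of contact i — its allosteric-community
trace — is the sum of the optimized per-edge MI values over its graph
neighborhood Gamma_i:

    D_i(t) = sum_{j in Gamma_i} MI_t(i, j | delta_ij(t))
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import FingerprintMatrix
from .network import UniversalGraph

__all__ = [
    "WindowGrid",
    "TRACTrace",
    "windowed_mi",
    "optimize_window",
    "trac_traces",
]

DEFAULT_WINDOW_SIZES = (150, 300, 450, 600, 750, 900, 1050)
DEFAULT_STRIDE = 10


@dataclass(frozen=True)
class WindowGrid:
    """Candidate sliding-window sizes (full widths, frames) and the stride of
    evaluation times.  Full widths must be even (half-width convention) and
    ascending."""

    sizes: tuple[int, ...] = DEFAULT_WINDOW_SIZES
    stride: int = DEFAULT_STRIDE

    def __post_init__(self) -> None:
        if not self.sizes:
            raise ValueError("window grid must contain at least one size")
        if any(s % 2 for s in self.sizes):
            raise ValueError("full window sizes must be even")
        if list(self.sizes) != sorted(set(self.sizes)):
            raise ValueError("window sizes must be strictly ascending")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    @property
    def half_widths(self) -> tuple[int, ...]:
        return tuple(s // 2 for s in self.sizes)

    def evaluation_times(self, n_frames: int) -> np.ndarray:
        """Times where the smallest window fits: [delta_min, n - delta_min]."""
        d = self.half_widths[0]
        if n_frames < 2 * d:
            raise ValueError(
                f"trajectory of {n_frames} frames shorter than smallest window {2 * d}"
            )
        return np.arange(d, n_frames - d + 1, self.stride)


def _mi_from_counts(n11, n10, n01, n00):
    """Vectorized plug-in MI (bits) from the four 2x2 cell counts."""
    n11, n10, n01, n00 = (np.asarray(a, dtype=np.float64) for a in (n11, n10, n01, n00))
    n = n11 + n10 + n01 + n00
    r1 = n11 + n10  # x = 1
    r0 = n01 + n00
    c1 = n11 + n01  # y = 1
    c0 = n10 + n00
    mi = np.zeros_like(n, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        for cnt, rm, cm in ((n11, r1, c1), (n10, r1, c0), (n01, r0, c1), (n00, r0, c0)):
            term = cnt / n * np.log2(cnt * n / (rm * cm))
            mi += np.where(cnt > 0, np.nan_to_num(term, nan=0.0, posinf=0.0, neginf=0.0), 0.0)
    return np.maximum(mi, 0.0)


def _miller_madow_term(n11, n10, n01, n00):
    """Vectorized Miller-Madow MI correction (bits): the entropy corrections
    (m - 1) / (2 N ln 2) of the two marginals minus the joint, with m the
    number of occupied cells."""
    n11, n10, n01, n00 = (np.asarray(a, dtype=np.float64) for a in (n11, n10, n01, n00))
    n = n11 + n10 + n01 + n00
    mx = ((n11 + n10) > 0).astype(float) + ((n01 + n00) > 0)
    my = ((n11 + n01) > 0).astype(float) + ((n10 + n00) > 0)
    mxy = (n11 > 0).astype(float) + (n10 > 0) + (n01 > 0) + (n00 > 0)
    return (mx + my - mxy - 1.0) / (2.0 * n * np.log(2.0))


def windowed_mi(
    x: np.ndarray, y: np.ndarray, t: int, half_width: int, bias_correction: bool = False
) -> float:
    """MI (bits) of two binary streams inside the window [t - delta, t + delta).

    ``bias_correction`` applies the Miller-Madow first-order correction for
    the upward bias of the plug-in estimate in short windows (off by
    default: the fixed bit thresholds are defined against the plain
    plug-in estimator)."""
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.size != y.size:
        raise ValueError("streams must have equal length")
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    lo, hi = t - half_width, t + half_width
    if lo < 0 or hi > x.size:
        raise ValueError(
            f"window [{lo}, {hi}) exceeds trajectory bounds [0, {x.size}); "
            f"restrict t to [{half_width}, {x.size - half_width}]"
        )
    xw = x[lo:hi].astype(bool)
    yw = y[lo:hi].astype(bool)
    n11 = int(np.count_nonzero(xw & yw))
    n10 = int(np.count_nonzero(xw & ~yw))
    n01 = int(np.count_nonzero(~xw & yw))
    n00 = xw.size - n11 - n10 - n01
    mi = float(_mi_from_counts(n11, n10, n01, n00))
    if bias_correction:
        mi = max(0.0, mi + float(_miller_madow_term(n11, n10, n01, n00)))
    return mi


def _mi_series(
    x: np.ndarray,
    y: np.ndarray,
    half_width: int,
    times: np.ndarray,
    bias_correction: bool = False,
) -> np.ndarray:
    """Windowed MI at many times for one half-width, via prefix sums.

    Entries where the window does not fit are NaN.
    """
    n = x.size
    cx = np.concatenate(([0], np.cumsum(x, dtype=np.int64)))
    cy = np.concatenate(([0], np.cumsum(y, dtype=np.int64)))
    cxy = np.concatenate(([0], np.cumsum((x & y).astype(np.int64))))
    lo = times - half_width
    hi = times + half_width
    ok = (lo >= 0) & (hi <= n)
    out = np.full(times.size, np.nan)
    if ok.any():
        l, h = lo[ok], hi[ok]
        n11 = cxy[h] - cxy[l]
        n1_ = cx[h] - cx[l]
        n_1 = cy[h] - cy[l]
        w = h - l
        cells = (n11, n1_ - n11, n_1 - n11, w - n1_ - n_1 + n11)
        mi = _mi_from_counts(*cells)
        if bias_correction:
            mi = np.maximum(0.0, mi + _miller_madow_term(*cells))
        out[ok] = mi
    return out


def optimize_window(
    x: np.ndarray,
    y: np.ndarray,
    t: int,
    grid: WindowGrid = WindowGrid(),
    bias_correction: bool = False,
) -> tuple[int, float] | None:
    """Maximize windowed MI over the grid at one time.

    Returns ``(chosen full window size, MI)``; ties go to the largest
    feasible window.  ``None`` when no grid size fits at ``t`` (the
    "not evaluable" sentinel).
    """
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    best: tuple[int, float] | None = None
    for size, delta in zip(grid.sizes, grid.half_widths):
        if t - delta < 0 or t + delta > x.size:
            continue
        mi = windowed_mi(x, y, t, delta, bias_correction)
        if best is None or mi >= best[1]:  # >= : later (larger) window wins ties
            best = (size, mi)
    return best


@dataclass
class TRACTrace:
    """Time-resolved weighted degree of one contact plus its per-edge parts.

    ``edge_mi[j]`` is the optimized windowed MI between the center and
    neighbor ``j`` at each evaluation time; ``values`` (= D_i(t)) is their
    sum, exact by construction.
    """

    node: str
    times: np.ndarray
    edge_mi: dict[str, np.ndarray] = field(default_factory=dict)
    edge_window: dict[str, np.ndarray] = field(default_factory=dict)
    trajectory_id: str = ""
    empty_neighborhood: bool = False

    @property
    def values(self) -> np.ndarray:
        if not self.edge_mi:
            return np.zeros(self.times.size)
        return np.sum(list(self.edge_mi.values()), axis=0)

    @property
    def max_amplitude(self) -> float:
        v = self.values
        return float(v.max()) if v.size else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, mi in self.edge_mi.items():
            win = self.edge_window[j]
            for t, m, w in zip(self.times, mi, win):
                rows.append((self.node, j, int(t), int(w), float(m)))
        return pd.DataFrame(rows, columns=["node", "neighbor", "t", "window", "mi_bits"])


def _optimized_edge_trace(
    x: np.ndarray,
    y: np.ndarray,
    times: np.ndarray,
    grid: WindowGrid,
    bias_correction: bool = False,
    window_mode: str = "per_time",
) -> tuple[np.ndarray, np.ndarray]:
    """Windowed-MI trace of one edge with the window optimized over the grid.

    ``per_time`` maximizes independently at each evaluation time;
    ``global`` commits to the single window size whose peak MI over the
    whole trajectory is largest, and uses that size everywhere it fits.
    Ties resolve toward the largest window in both modes.
    """
    if window_mode == "per_time":
        best_mi = np.full(times.size, -np.inf)
        best_w = np.zeros(times.size, dtype=int)
        for size, delta in zip(grid.sizes, grid.half_widths):
            mi = _mi_series(x, y, delta, times, bias_correction)
            take = ~np.isnan(mi) & (mi >= best_mi)
            best_mi[take] = mi[take]
            best_w[take] = size
        best_mi[~np.isfinite(best_mi)] = np.nan
        return best_mi, best_w
    if window_mode != "global":
        raise ValueError(f"unknown window_mode {window_mode!r}")
    series = {
        size: _mi_series(x, y, delta, times, bias_correction)
        for size, delta in zip(grid.sizes, grid.half_widths)
    }
    def peak(s: int) -> float:
        vals = series[s]
        return -np.inf if np.isnan(vals).all() else float(np.nanmax(vals))

    best_size = max(grid.sizes, key=lambda s: (peak(s), s))  # ties to the larger window
    chosen = series[best_size]
    win = np.full(times.size, best_size, dtype=int)
    # fall back to the largest feasible smaller window near the edges
    gap = np.isnan(chosen)
    for size in reversed([s for s in grid.sizes if s < best_size]):
        if not gap.any():
            break
        fill = series[size]
        usable = gap & ~np.isnan(fill)
        chosen = np.where(usable, fill, chosen)
        win[usable] = size
        gap = np.isnan(chosen)
    return chosen, win


def trac_traces(
    matrix: FingerprintMatrix,
    graph: UniversalGraph,
    grid: WindowGrid = WindowGrid(),
    bias_correction: bool = False,
    window_mode: str = "per_time",
) -> dict[str, TRACTrace]:
    """Compute D_i(t) for every graph node along one trajectory.

    Evaluation times are the stride grid where the smallest window fits, so
    every edge has a value at every evaluated time.  Per-edge traces are
    shared between the two endpoint nodes (computed once per edge).  Graph
    nodes missing from the trajectory's columns are treated as constant
    zero (their edges contribute 0 bits) with a warning.
    """
    times = grid.evaluation_times(matrix.n_frames)
    col = {lab: i for i, lab in enumerate(matrix.contact_labels)}
    missing = [n for n in graph.nodes if n not in col]
    if missing:
        warnings.warn(
            f"{len(missing)} graph nodes missing from trajectory "
            f"{matrix.trajectory_id!r}; treated as constant zero: {missing[:5]}...",
            stacklevel=2,
        )

    def stream(node: str) -> np.ndarray:
        if node in col:
            return matrix.values[:, col[node]].astype(np.int64)
        return np.zeros(matrix.n_frames, dtype=np.int64)

    edge_cache: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    traces: dict[str, TRACTrace] = {}
    for node in graph.nodes:
        tr = TRACTrace(node, times, trajectory_id=matrix.trajectory_id)
        neighbors = graph.neighbors(node)
        if not neighbors:
            tr.empty_neighborhood = True
        for j in neighbors:
            key = (node, j) if node < j else (j, node)
            if key not in edge_cache:
                edge_cache[key] = _optimized_edge_trace(
                    stream(key[0]), stream(key[1]), times, grid,
                    bias_correction, window_mode,
                )
            mi, win = edge_cache[key]
            tr.edge_mi[j] = mi
            tr.edge_window[j] = win
        traces[node] = tr
    return traces


def traces_summary(traces: dict[str, TRACTrace]) -> pd.DataFrame:
    """Per-node summary: max D_i(t) and its argmax time."""
    rows = []
    for node, tr in traces.items():
        v = tr.values
        if v.size:
            amax = int(tr.times[int(np.argmax(v))])
            rows.append((node, float(v.max()), amax, len(tr.edge_mi)))
        else:
            rows.append((node, 0.0, -1, len(tr.edge_mi)))
    return pd.DataFrame(rows, columns=["node", "max_degree_bits", "argmax_t", "n_neighbors"])
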