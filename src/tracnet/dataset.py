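"""Universal dataset construction.

A probabilistic graph over contacts is learned not from one trajectory but
from an ensemble.  Two routes produce the row-sampled "universal" table
D^U over the significant contact set C:

* plain concatenation of all trajectories, or
* enriched subsampling: frames drawn with replacement from a fixed-width
  region centered on each trajectory's macro-transition, located on a 1-D
  transition-proxy trace (e.g. a TM3-TM6 interhelical distance) via a
  least-squares single change point.

Row provenance (trajectory, source frame) is kept throughout so every
sampled row can be traced back to its origin.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import FingerprintMatrix

__all__ = [
    "TransitionTrace",
    "UniversalDataset",
    "moving_average",
    "detect_transition",
    "enriched_sample",
    "concatenate",
    "read_trace",
]

DEFAULT_REGION_FRAMES = 5000
#: Warn above these dataset sizes: network-structure search is worst-case
#: exponential and this scale is near the practical single-run limit.
BUDGET_CONTACTS = 1000
BUDGET_ROWS = 15000


@dataclass
class TransitionTrace:
    """One real value per frame of a transition proxy, plus its smoothing window."""

    values: np.ndarray
    smoothing_window: int = 1
    trajectory_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class UniversalDataset:
    """Rows x |C| binary table with per-row (trajectory, frame) provenance."""

    values: np.ndarray
    contact_labels: list[str]
    provenance: pd.DataFrame  # columns: trajectory_id, source_frame
    sampling_config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("dataset entries must be 0 or 1")
        if len(self.provenance) != self.values.shape[0]:
            raise ValueError("provenance length must equal row count")
        if self.values.shape[0] > BUDGET_ROWS or self.values.shape[1] > BUDGET_CONTACTS:
            warnings.warn(
                f"dataset of {self.values.shape[0]} rows x {self.values.shape[1]} "
                f"contacts exceeds the practical structure-search budget "
                f"(~{BUDGET_ROWS} rows, ~{BUDGET_CONTACTS} contacts)",
                stacklevel=2,
            )

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.contact_labels.index(label)]


def moving_average(trace: TransitionTrace | np.ndarray, window: int) -> np.ndarray:
    """Centered simple moving average with shrinking edge windows.

    At the edges the mean is taken over the available part of the window, so
    the output has the same length as the input and a window of 1 is the
    identity.
    """
    values = trace.values if isinstance(trace, TransitionTrace) else np.asarray(trace, float)
    n = values.size
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > n:
        raise ValueError(f"window {window} exceeds trace length {n}")
    return (
        pd.Series(values).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def detect_transition(trace: TransitionTrace) -> int | None:
    """Locate the macro-transition as a least-squares single change point.

    The smoothed trace is split into two segments; the split minimizing the
    total within-segment sum of squared deviations is returned as the first
    frame of the second segment.  A constant trace has no transition and
    returns ``None``.
    """
    if len(trace) < 10:
        raise ValueError("trace too short for change-point detection (need >= 10 frames)")
    y = moving_average(trace, trace.smoothing_window)
    if np.allclose(y, y[0]):
        return None
    n = y.size
    # prefix sums give each candidate split in O(1):
    # SSE(a:b) = sum(y^2) - (sum y)^2 / (b - a)
    c1 = np.concatenate(([0.0], np.cumsum(y)))
    c2 = np.concatenate(([0.0], np.cumsum(y * y)))
    k = np.arange(1, n)  # first frame of the right segment
    left = c2[k] - c1[k] ** 2 / k
    right = (c2[n] - c2[k]) - (c1[n] - c1[k]) ** 2 / (n - k)
    sse = left + right
    return int(k[np.argmin(sse)])


def enriched_sample(
    ensemble: list[FingerprintMatrix],
    transitions: list[int],
    n_per_traj: int,
    region: int = DEFAULT_REGION_FRAMES,
    seed: int = 0,
) -> UniversalDataset:
    """Sample ``n_per_traj`` frames with replacement per trajectory, uniformly
    from a ``region``-frame window centered on that trajectory's transition.

    The window is [t* - region/2, t* + region/2) clipped to the trajectory
    bounds.  Each trajectory uses its own seeded generator stream
    (``seed + trajectory index``) so draws are reproducible regardless of
    ensemble composition elsewhere.
    """
    if len(transitions) != len(ensemble):
        raise ValueError("one transition frame per trajectory required")
    if n_per_traj < 1:
        raise ValueError("n_per_traj must be >= 1")
    labels = ensemble[0].contact_labels
    for m in ensemble[1:]:
        if m.contact_labels != labels:
            raise ValueError("all ensemble matrices must share the contact set C")
    blocks, prov_rows = [], []
    half = region // 2
    for idx, (matrix, t_star) in enumerate(zip(ensemble, transitions)):
        lo = max(0, int(t_star) - half)
        hi = min(matrix.n_frames, int(t_star) + half)
        if hi <= lo:
            raise ValueError(
                f"trajectory {matrix.trajectory_id!r}: sampling region empty after clipping"
            )
        rng = np.random.default_rng(seed + idx)
        frames = rng.integers(lo, hi, size=n_per_traj)
        blocks.append(matrix.values[frames])
        prov_rows.append(
            pd.DataFrame(
                {"trajectory_id": matrix.trajectory_id or str(idx), "source_frame": frames}
            )
        )
    return UniversalDataset(
        np.vstack(blocks),
        list(labels),
        pd.concat(prov_rows, ignore_index=True),
        sampling_config={
            "mode": "enriched",
            "region": region,
            "n_per_traj": n_per_traj,
            "seed": seed,
        },
    )


def concatenate(ensemble: list[FingerprintMatrix]) -> UniversalDataset:
    """Stack whole trajectories (restricted to C) into one dataset."""
    if not ensemble:
        raise ValueError("empty ensemble")
    labels = ensemble[0].contact_labels
    for m in ensemble[1:]:
        if m.contact_labels != labels:
            raise ValueError(
                "label sets differ; restrict all matrices to C first "
                "(zero-fill absences in union mode)"
            )
    prov = pd.concat(
        [
            pd.DataFrame(
                {
                    "trajectory_id": m.trajectory_id or str(i),
                    "source_frame": np.arange(m.n_frames),
                }
            )
            for i, m in enumerate(ensemble)
        ],
        ignore_index=True,
    )
    return UniversalDataset(
        np.vstack([m.values for m in ensemble]),
        list(labels),
        prov,
        sampling_config={"mode": "concatenate"},
    )


def read_trace(path, smoothing_window: int = 1, trajectory_id: str = "") -> TransitionTrace:
    """Read a one-value-per-frame proxy trace from single-column text/CSV."""
    values = pd.read_csv(path, header=None).iloc[:, -1].to_numpy(dtype=float)
    return TransitionTrace(values, smoothing_window, trajectory_id)
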