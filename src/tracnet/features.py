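"""Filter-based feature selection for contact fingerprints.

Reduces the full contact set C_all of a trajectory ensemble to the
significant set C: sequence-neighbor contacts are excluded, then contacts
whose pairwise mutual information with every other contact stays below a
fixed bit threshold are dropped, and per-trajectory survivor sets are
combined (intersection by default) into the final C.

All mutual information here is the plug-in estimate from the empirical
2x2 contingency table in bits (log base 2), with 0*log(0) == 0.  No bias
correction is applied: the filter threshold is defined against the plain
plug-in estimator.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import FingerprintMatrix, parse_pair_label

__all__ = [
    "FeatureSelectionReport",
    "exclude_neighbors",
    "pairwise_mi",
    "mi_matrix",
    "mi_filter",
    "combine_features",
]

DEFAULT_MI_THRESHOLD_BITS = 0.01
DEFAULT_MIN_SEPARATION = 1


@dataclass
class FeatureSelectionReport:
    """Per-trajectory audit of which contacts survived and why not."""

    trajectory_id: str
    kept: list[str]
    dropped: dict[str, str] = field(default_factory=dict)  # label -> reason
    max_mi: dict[str, float] = field(default_factory=dict)
    threshold_bits: float = DEFAULT_MI_THRESHOLD_BITS

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lab in self.kept:
            rows.append((lab, self.trajectory_id, True, "", self.max_mi.get(lab, np.nan)))
        for lab, reason in self.dropped.items():
            rows.append((lab, self.trajectory_id, False, reason, self.max_mi.get(lab, np.nan)))
        return pd.DataFrame(
            rows, columns=["contact", "trajectory", "kept", "reason", "max_mi_bits"]
        )


def exclude_neighbors(
    matrix: FingerprintMatrix, min_separation: int = DEFAULT_MIN_SEPARATION
) -> FingerprintMatrix:
    """Drop contacts between sequence neighbors.

    An intra-chain contact is removed when |resid_a - resid_b| <= min_separation;
    inter-chain contacts are always kept.  Labels that do not parse as residue
    pairs are reported together in one error.
    """
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    keep: list[str] = []
    bad: list[str] = []
    for lab in matrix.contact_labels:
        try:
            a, b, _ = parse_pair_label(lab)
        except ValueError:
            bad.append(lab)
            continue
        if a.chain != b.chain or abs(a.resid - b.resid) > min_separation:
            keep.append(lab)
    if bad:
        raise ValueError(f"unparsable residue indices in labels: {bad}")
    return matrix.restrict(keep)


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def pairwise_mi(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (bits) of two binary columns."""
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n == 0:
        raise ValueError("empty columns")
    n11 = int(np.count_nonzero((x == 1) & (y == 1)))
    n10 = int(np.count_nonzero((x == 1) & (y == 0)))
    n01 = int(np.count_nonzero((x == 0) & (y == 1)))
    n00 = n - n11 - n10 - n01
    if n11 + n10 in (0, n) or n11 + n01 in (0, n):
        return 0.0  # a constant column carries no information
    px = (n11 + n10) / n
    py = (n11 + n01) / n
    marginals = {
        (1, 1): px * py,
        (1, 0): px * (1 - py),
        (0, 1): (1 - px) * py,
        (0, 0): (1 - px) * (1 - py),
    }
    counts = {(1, 1): n11, (1, 0): n10, (0, 1): n01, (0, 0): n00}
    terms = [
        (c / n) * math.log2((c / n) / marginals[cell])
        for cell, c in counts.items()
        if c > 0
    ]
    # summing the sorted terms makes the estimate exactly symmetric in (x, y)
    return max(0.0, math.fsum(sorted(terms)))


def mi_matrix(values: np.ndarray, block_size: int = 256) -> np.ndarray:
    """Full symmetric pairwise-MI matrix (bits) of a binary frames x p matrix.

    Computed blockwise from the four joint counts; the result is independent
    of ``block_size`` (only memory traffic changes).  The diagonal holds each
    column's entropy H(x) = MI(x, x).
    """
    X = np.asarray(values, dtype=np.float64)
    n, p = X.shape
    out = np.empty((p, p), dtype=np.float64)
    ones = X.sum(axis=0)
    for start in range(0, p, block_size):
        stop = min(start + block_size, p)
        B = X[:, start:stop]
        n11 = B.T @ X  # (block, p)
        n1_ = ones[start:stop][:, None]
        n_1 = ones[None, :]
        n10 = n1_ - n11
        n01 = n_1 - n11
        n00 = n - n11 - n10 - n01
        with np.errstate(divide="ignore", invalid="ignore"):
            mi = np.zeros_like(n11)
            for cnt, rowm, colm in (
                (n11, n1_, n_1),
                (n10, n1_, n - n_1),
                (n01, n - n1_, n_1),
                (n00, n - n1_, n - n_1),
            ):
                term = cnt / n * np.log2(cnt * n / (rowm * colm))
                mi += np.where(cnt > 0, np.nan_to_num(term, nan=0.0, posinf=0.0, neginf=0.0), 0.0)
        out[start:stop] = np.maximum(mi, 0.0)
    return out


def mi_filter(
    matrix: FingerprintMatrix,
    threshold: float = DEFAULT_MI_THRESHOLD_BITS,
    block_size: int = 256,
) -> tuple[FingerprintMatrix, FeatureSelectionReport]:
    """Keep a contact iff its best pairwise MI with another contact exceeds
    ``threshold`` bits.  Constant columns carry zero information and are
    always dropped (reason "constant")."""
    if matrix.n_contacts < 2:
        raise ValueError("mi_filter needs at least two contacts")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    mi = mi_matrix(matrix.values, block_size=block_size)
    np.fill_diagonal(mi, -np.inf)
    best = mi.max(axis=1)
    col_sums = matrix.values.sum(axis=0)
    constant = (col_sums == 0) | (col_sums == matrix.n_frames)
    report = FeatureSelectionReport(matrix.trajectory_id, [], threshold_bits=threshold)
    kept: list[str] = []
    for j, lab in enumerate(matrix.contact_labels):
        report.max_mi[lab] = float(best[j]) if np.isfinite(best[j]) else 0.0
        if constant[j]:
            report.dropped[lab] = "constant"
        elif best[j] > threshold:
            kept.append(lab)
        else:
            report.dropped[lab] = "low-MI"
    report.kept = kept
    return matrix.restrict(kept), report


def combine_features(
    per_trajectory_kept: list[set[str] | list[str]], mode: str = "intersection"
) -> list[str]:
    """Combine per-trajectory survivor sets into the final contact set C.

    ``intersection`` keeps labels retained in every trajectory; ``union``
    keeps labels retained in any (downstream code zero-fills absences).
    Returned sorted for a stable canonical order.
    """
    if not per_trajectory_kept:
        raise ValueError("need at least one trajectory feature set")
    sets = [set(s) for s in per_trajectory_kept]
    if mode == "intersection":
        combined = set.intersection(*sets)
    elif mode == "union":
        combined = set.union(*sets)
    else:
        raise ValueError(f"unknown combine mode {mode!r}")
    if not combined:
        raise ValueError(
            "combined contact set is empty; relax the MI threshold or use union mode"
        )
    return sorted(combined)
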