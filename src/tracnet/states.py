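"""Conformational-state delineation from a contact subnetwork.

Frames are projected onto the principal components of the binary
fingerprint restricted to a selected contact subset (e.g. the combined
enabler + effector subnetwork).  Columns are centered but not scaled:
unit-variance scaling of 0/1 columns over-weights rarely formed contacts.
A seeded k-means step then partitions the score space into discrete
states, renumbered in temporal order of first occurrence so state 1 is
always where the trajectory starts.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import FingerprintMatrix

__all__ = ["StateProjection", "pca_project", "assign_states"]


@dataclass
class StateProjection:
    """PCA scores/loadings of one trajectory over a contact subset."""

    scores: np.ndarray  # frames x k
    loadings: np.ndarray  # contacts x k, columns orthonormal
    explained_variance_ratio: np.ndarray
    contact_labels: list[str]
    state_labels: np.ndarray | None = None

    def top_loading_contacts(self, component: int, n: int = 10) -> pd.DataFrame:
        w = self.loadings[:, component]
        order = np.argsort(-np.abs(w))[:n]
        return pd.DataFrame(
            {"contact": [self.contact_labels[i] for i in order], "loading": w[order]}
        )


def pca_project(matrix: FingerprintMatrix, k: int = 2) -> StateProjection:
    """Column-centered PCA of a fingerprint via SVD.

    Deterministic up to component sign; the sign is fixed by making each
    loading column's largest-magnitude entry positive.  ``k`` may not
    exceed the rank of the centered matrix.
    """
    X = matrix.values.astype(float)
    n_nonconstant = int((X.std(axis=0) > 0).sum())
    if n_nonconstant < k:
        raise ValueError(
            f"need >= {k} non-constant contacts for {k} components, have {n_nonconstant}"
        )
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    # deterministic sign convention
    for i in range(k):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    scores = U[:, :k] * s[:k]
    total_var = (s**2).sum()
    evr = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    return StateProjection(scores, Vt[:k].T, evr, list(matrix.contact_labels))


def assign_states(
    projection: StateProjection, n_states: int = 3, seed: int = 0
) -> np.ndarray:
    """Seeded k-means partition of score space, renumbered temporally.

    Labels are 1-based and ordered by first occurrence along the
    trajectory, so the first frame always belongs to state 1.
    """
    from sklearn.cluster import KMeans

    X = projection.scores
    if n_states < 1 or n_states > X.shape[0]:
        raise ValueError("n_states must be in [1, n_frames]")
    n_distinct = np.unique(X, axis=0).shape[0]
    if n_distinct < n_states:
        raise ValueError(
            f"only {n_distinct} distinct score points for {n_states} states"
        )
    km = KMeans(n_clusters=n_states, n_init=10, random_state=seed, max_iter=300)
    raw = km.fit_predict(X)
    # renumber by first occurrence
    remap: dict[int, int] = {}
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    labels = np.array([remap[lab] for lab in raw], dtype=int)
    projection.state_labels = labels
    return labels
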