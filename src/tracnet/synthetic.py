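"""Synthetic fixtures with the statistical structure the pipeline assumes.

Two generators:

* :func:`generate_ensemble` — multi-trajectory binary contact streams with
  planted dependency communities.  Each community follows a latent
  two-state signal that switches once (the "enabler" community early at
  t_e, the "effector" community later at t_f, jittered per trajectory);
  members copy the latent state with probability equal to the coupling and
  otherwise draw a fair coin.  Background contacts are independent
  two-state Markov chains, so windowed MI faces realistic autocorrelation
  rather than i.i.d. noise.  A transition-proxy trace (emulating a TM3-TM6
  interhelical distance) steps down at the effector switch.

* :func:`generate_msa` — toy labeled alignments with planted fully
  conserved and class-specific columns for the conservation/specificity
  round trip.

Defaults reflect a desk-scale study condition: 12 trajectories of 8,000
frames over 40 contacts, two planted communities of 5 at coupling 0.95
switching at 3,000 and 5,000 frames (jitter 200), 30 background contacts.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contacts import FingerprintMatrix, ResidueID, pair_label
from .dataset import TransitionTrace
from .evolution import AMINO_ACIDS, LabeledMSA

__all__ = ["SyntheticTruth", "generate_ensemble", "generate_msa"]

DEFAULT_N_TRAJECTORIES = 12
DEFAULT_N_FRAMES = 8000
DEFAULT_N_CONTACTS = 40
DEFAULT_COMMUNITIES = ((5, 0.95), (5, 0.95))
DEFAULT_T_ENABLER = 3000
DEFAULT_T_EFFECTOR = 5000
DEFAULT_JITTER = 200
DEFAULT_FLIP_RATE = 0.02

_RESNAMES = ("ALA", "GLY", "LEU", "SER", "VAL", "THR", "PHE", "ARG", "GLU", "LYS")


@dataclass
class SyntheticTruth:
    """Ground truth of a planted ensemble."""

    community_of: dict[str, int]  # contact label -> community index (-1: background)
    planted_edges: set[tuple[str, str]]  # undirected, within-community, sorted pairs
    switch_times: list[dict[int, int]]  # per trajectory: community -> switch frame
    couplings: dict[int, float]
    seed: int

    def members(self, community: int) -> list[str]:
        return sorted(l for l, c in self.community_of.items() if c == community)


def _contact_labels(n_contacts: int, rng: np.random.Generator) -> list[str]:
    """Plausible residue-pair labels, all non-neighboring (|resid gap| >= 5)."""
    labels: set[str] = set()
    while len(labels) < n_contacts:
        r1 = int(rng.integers(10, 300))
        r2 = r1 + int(rng.integers(5, 150))
        a = ResidueID("A", _RESNAMES[r1 % len(_RESNAMES)], r1)
        b = ResidueID("A", _RESNAMES[r2 % len(_RESNAMES)], r2)
        labels.add(pair_label(a, b))
    return sorted(labels)[:n_contacts]


def generate_ensemble(
    n_trajectories: int = DEFAULT_N_TRAJECTORIES,
    n_frames: int = DEFAULT_N_FRAMES,
    n_contacts: int = DEFAULT_N_CONTACTS,
    communities: tuple[tuple[int, float], ...] = DEFAULT_COMMUNITIES,
    t_enabler: int = DEFAULT_T_ENABLER,
    t_effector: int = DEFAULT_T_EFFECTOR,
    jitter: int = DEFAULT_JITTER,
    baseline_flip_rate: float = DEFAULT_FLIP_RATE,
    seed: int = 0,
) -> tuple[list[FingerprintMatrix], list[TransitionTrace], SyntheticTruth]:
    """Planted-community contact ensemble with a coordinated macro-transition.

    ``communities`` is a tuple of (size, coupling) pairs; the first
    community switches at ``t_enabler``, the remaining ones at
    ``t_effector`` (each jittered per trajectory by +/- ``jitter`` frames).
    Community members are 1 before their switch and 0 after, copied with
    probability ``coupling`` and replaced by a fair coin otherwise.
    Background contacts flip state with ``baseline_flip_rate`` per frame.
    """
    sizes = [s for s, _ in communities]
    if sum(sizes) > n_contacts:
        raise ValueError("community sizes exceed n_contacts")
    if not (t_enabler + jitter < t_effector - jitter):
        raise ValueError(
            "infeasible timing: enabler window must end before effector window"
        )
    if not 0 <= baseline_flip_rate <= 1:
        raise ValueError("baseline_flip_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = _contact_labels(n_contacts, rng)
    community_of = {lab: -1 for lab in labels}
    couplings: dict[int, float] = {}
    planted_edges: set[tuple[str, str]] = set()
    cursor = 0
    members: dict[int, list[str]] = {}
    for ci, (size, coupling) in enumerate(communities):
        mem = labels[cursor : cursor + size]
        cursor += size
        members[ci] = mem
        couplings[ci] = coupling
        for lab in mem:
            community_of[lab] = ci
        for i, a in enumerate(mem):
            for b in mem[i + 1 :]:
                planted_edges.add(tuple(sorted((a, b))))

    matrices: list[FingerprintMatrix] = []
    traces: list[TransitionTrace] = []
    switch_times: list[dict[int, int]] = []
    col = {lab: j for j, lab in enumerate(labels)}
    for k in range(n_trajectories):
        trng = np.random.default_rng(seed + 1000 + k)
        values = np.zeros((n_frames, n_contacts), dtype=np.uint8)
        switches: dict[int, int] = {}
        for ci, (size, coupling) in enumerate(communities):
            base = t_enabler if ci == 0 else t_effector
            t_sw = base + (int(trng.integers(-jitter, jitter + 1)) if jitter else 0)
            switches[ci] = t_sw
            latent = (np.arange(n_frames) < t_sw).astype(np.uint8)
            for lab in members[ci]:
                if coupling >= 1.0:
                    stream = latent.copy()
                else:
                    follow = trng.random(n_frames) < coupling
                    coin = trng.integers(0, 2, n_frames).astype(np.uint8)
                    stream = np.where(follow, latent, coin).astype(np.uint8)
                values[:, col[lab]] = stream
        # background: stationary two-state Markov chains
        n_bg = n_contacts - cursor
        if n_bg:
            flips = trng.random((n_frames, n_bg)) < baseline_flip_rate
            start = trng.integers(0, 2, n_bg).astype(np.uint8)
            bg = (np.cumsum(flips, axis=0) % 2).astype(np.uint8) ^ start[None, :]
            values[:, cursor:] = bg
        matrices.append(FingerprintMatrix(values, labels, trajectory_id=f"traj{k}"))
        # proxy trace: high before the effector switch, low after, mild noise
        t_f = switches[max(switches)] if len(switches) > 1 else switches[0]
        proxy = np.where(np.arange(n_frames) < t_f, 12.0, 7.0)
        proxy = proxy + trng.normal(0.0, 0.4, n_frames)
        traces.append(TransitionTrace(proxy, smoothing_window=51, trajectory_id=f"traj{k}"))
        switch_times.append(switches)
    truth = SyntheticTruth(community_of, planted_edges, switch_times, couplings, seed)
    return matrices, traces, truth


def generate_msa(
    n_per_class: int,
    classes: list[str],
    L: int,
    conserved_positions: list[int],
    specific_positions: dict[str, list[int]],
    background_diversity: int = 3,
    seed: int = 0,
) -> tuple[LabeledMSA, dict]:
    """Toy labeled alignment with planted conserved / class-specific columns.

    ``conserved_positions`` share one residue everywhere; each position in
    ``specific_positions[k]`` is invariant within class k and drawn from a
    disjoint residue pool in every other class.  Background columns sample
    ``background_diversity`` residue types per column (1 = invariant within
    the whole column).  Positions are 1-based.
    """
    rng = np.random.default_rng(seed)
    planted = set(conserved_positions)
    for k, pos in specific_positions.items():
        if k not in classes:
            raise ValueError(f"specific class {k!r} not in classes")
        overlap = planted & set(pos)
        if overlap:
            raise ValueError(f"planted position sets overlap at {sorted(overlap)}")
        planted |= set(pos)
    if any(not 1 <= p <= L for p in planted):
        raise ValueError(f"planted positions must lie in [1, {L}]")
    if background_diversity < 1 or background_diversity > 20:
        raise ValueError("background_diversity must be in [1, 20]")

    n_seqs = n_per_class * len(classes)
    labels = [c for c in classes for _ in range(n_per_class)]
    columns: list[list[str]] = []
    specific_at = {p: k for k, pos in specific_positions.items() for p in pos}
    for p in range(1, L + 1):
        if p in set(conserved_positions):
            aa = AMINO_ACIDS[int(rng.integers(0, 20))]
            columns.append([aa] * n_seqs)
        elif p in specific_at:
            k = specific_at[p]
            pool = rng.permutation(list(AMINO_ACIDS))
            class_aa = pool[0]
            other_pool = pool[1:]
            if len(classes) > 1 and other_pool.size == 0:
                raise ValueError("residue pool exhausted")
            colvals = []
            for lab in labels:
                if lab == k:
                    colvals.append(class_aa)
                else:
                    colvals.append(str(rng.choice(other_pool)))
            columns.append(colvals)
        else:
            pool = rng.choice(list(AMINO_ACIDS), size=background_diversity, replace=False)
            columns.append([str(rng.choice(pool)) for _ in range(n_seqs)])
    seqs = ["".join(columns[p][s] for p in range(L)) for s in range(n_seqs)]
    msa = LabeledMSA(seqs, labels)
    planted_sets = {
        "conserved": sorted(conserved_positions),
        "specific": {k: sorted(v) for k, v in specific_positions.items()},
    }
    return msa, planted_sets
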