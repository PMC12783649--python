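import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_ensemble():
    """3 trajectories x 3000 frames x 16 contacts with two planted
    communities of 4 (enabler switching at ~1100, effector at ~1900)."""
    from tracnet import generate_ensemble

    return generate_ensemble(
        n_trajectories=3,
        n_frames=3000,
        n_contacts=16,
        communities=((4, 0.95), (4, 0.95)),
        t_enabler=1100,
        t_effector=1900,
        jitter=50,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_analysis(small_ensemble):
    """Feature selection + universal dataset + graph + traces for the small
    ensemble, shared across signal/time-resolved tests."""
    from tracnet import (
        combine_features,
        detect_transition,
        edge_strengths,
        enriched_sample,
        exclude_neighbors,
        learn_structure,
        mi_filter,
        trac_traces,
    )

    matrices, traces, truth = small_ensemble
    kept = []
    for m in matrices:
        m2 = exclude_neighbors(m)
        _, report = mi_filter(m2)
        kept.append(set(report.kept))
    contact_set = combine_features(kept)
    restricted = [m.restrict(contact_set) for m in matrices]
    transitions = [detect_transition(t) for t in traces]
    data = enriched_sample(restricted, transitions, n_per_traj=800, region=2000, seed=11)
    graph = learn_structure(data, restarts=2, seed=11)
    edge_strengths(graph, data)
    all_traces = {m.trajectory_id: trac_traces(m, graph) for m in restricted}
    return {
        "matrices": restricted,
        "truth": truth,
        "dataset": data,
        "graph": graph,
        "traces": all_traces,
    }


def mi_2x2_oracle(n11: int, n10: int, n01: int, n00: int) -> float:
    """Independent brute-force plug-in MI (bits) over the four cells."""
    import math

    n = n11 + n10 + n01 + n00
    p = {
        (1, 1): n11 / n,
        (1, 0): n10 / n,
        (0, 1): n01 / n,
        (0, 0): n00 / n,
    }
    px = {1: p[1, 1] + p[1, 0], 0: p[0, 1] + p[0, 0]}
    py = {1: p[1, 1] + p[0, 1], 0: p[1, 0] + p[0, 0]}
    total = 0.0
    for (a, b), pab in p.items():
        if pab > 0:
            total += pab * math.log2(pab / (px[a] * py[b]))
    return total


@pytest.fixture(scope="session")
def mi_oracle():
    return mi_2x2_oracle


def skeleton_f1(true_edges: set, learned_edges: set) -> float:
    """F1 of undirected edge recovery."""
    t = {tuple(sorted(e)) for e in true_edges}
    l = {tuple(sorted(e)) for e in learned_edges}
    if not l and not t:
        return 1.0
    tp = len(t & l)
    prec = tp / len(l) if l else 0.0
    rec = tp / len(t) if t else 0.0
    if prec + rec == 0:
        return 0.0
    return 2 * prec * rec / (prec + rec)
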