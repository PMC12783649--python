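"""Probabilistic-graph (Bayesian network) learning over binary contacts.

The universal graph G = (C, E) is a directed acyclic graphical model whose
joint distribution factorizes as the product over contacts of
p(c_i | parents(c_i)).  The structure is found by score-based greedy hill
climbing (add / delete / reverse moves, seeded random restarts) maximizing
a decomposable BIC/MDL score:

    family_score(c | pa) = max log-likelihood  -  (ln n / 2) * 2^|pa|

with the multinomial likelihood of the binary child given each parent
configuration.  The log-likelihood is in natural log units; the number of
free parameters of a binary child with k binary parents is 2^k.

Downstream analysis only needs undirected adjacency and per-edge strengths:
strength is defined as the plug-in pairwise mutual information (bits) of
the edge endpoints over the universal dataset, so that static strengths and
the time-resolved rescoring share one unit.  The weighted degree D_i of a
node is the sum of strengths over incident edges, direction ignored.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import UniversalDataset
from .features import pairwise_mi

__all__ = [
    "UniversalGraph",
    "family_score",
    "learn_structure",
    "edge_strengths",
    "weighted_degree",
]

DEFAULT_MAX_PARENTS = 3
_EPS = 1e-9  # minimum score gain for a hill-climbing move


@dataclass
class UniversalGraph:
    """Directed acyclic graph over contact labels with optional edge strengths."""

    nodes: list[str]
    edges: set[tuple[str, str]] = field(default_factory=set)  # (parent, child)
    edge_strength: dict[tuple[str, str], float] = field(default_factory=dict)
    node_score: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.nodes)
        for p, c in self.edges:
            if p not in known or c not in known:
                raise ValueError(f"edge ({p}, {c}) references unknown node")
        if self._find_cycle():
            raise ValueError("graph contains a directed cycle")

    def parents(self, node: str) -> list[str]:
        return sorted(p for p, c in self.edges if c == node)

    def children(self, node: str) -> list[str]:
        return sorted(c for p, c in self.edges if p == node)

    def neighbors(self, node: str) -> list[str]:
        """Undirected adjacency Gamma_i = parents union children."""
        out = {p for p, c in self.edges if c == node}
        out |= {c for p, c in self.edges if p == node}
        out.discard(node)
        return sorted(out)

    def _find_cycle(self) -> bool:
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        for p, c in self.edges:
            children[p].append(c)
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {n: WHITE for n in self.nodes}

        def visit(u: str) -> bool:
            color[u] = GRAY
            for v in children[u]:
                if color[v] == GRAY or (color[v] == WHITE and visit(v)):
                    return True
            color[u] = BLACK
            return False

        return any(color[n] == WHITE and visit(n) for n in self.nodes)

    def total_score(self) -> float:
        return float(sum(self.node_score.values()))

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(*e, strength_bits=self.edge_strength.get(e))
        return g

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (p, c, self.edge_strength.get((p, c), np.nan))
            for p, c in sorted(self.edges)
        ]
        return pd.DataFrame(rows, columns=["parent", "child", "strength_bits"])

    def write_edges_tsv(self, path) -> None:
        self.edge_table().to_csv(path, sep="\t", index=False)

    def write_gml(self, path) -> None:
        import networkx as nx

        g = self.to_networkx()
        for e, s in self.edge_strength.items():
            g.edges[e]["strength_bits"] = float(s)
        nx.write_gml(g, path)

    @classmethod
    def from_edges_tsv(cls, path) -> "UniversalGraph":
        df = pd.read_csv(path, sep="\t")
        nodes = sorted(set(df["parent"]) | set(df["child"]))
        edges = {(p, c) for p, c in zip(df["parent"], df["child"])}
        strengths = {
            (p, c): float(s)
            for p, c, s in zip(df["parent"], df["child"], df["strength_bits"])
            if np.isfinite(s)
        }
        return cls(nodes, edges, strengths)


# ---------------------------------------------------------------------------
# scoring


def _family_score_arrays(
    child: np.ndarray, parents: np.ndarray | None, max_parents: int | None = None
) -> float:
    """BIC family score from raw 0/1 arrays (natural-log likelihood)."""
    n = child.size
    k = 0 if parents is None or parents.size == 0 else parents.shape[1]
    if max_parents is not None and k > max_parents:
        raise ValueError(
            f"{k} parents exceed max_parents={max_parents} (2^{k} configuration cells)"
        )
    if k == 0:
        code = child.astype(np.int64)
        n_cells = 2
    else:
        weights = (1 << np.arange(k, dtype=np.int64)) * 2
        code = parents.astype(np.int64) @ weights + child
        n_cells = 1 << (k + 1)
    joint = np.bincount(code, minlength=n_cells).astype(float)
    cfg = joint[0::2] + joint[1::2]  # counts per parent configuration
    nz = joint > 0
    loglik = float((joint[nz] * np.log(joint[nz] / np.repeat(cfg, 2)[nz])).sum())
    penalty = 0.5 * math.log(n) * (1 << k)
    return loglik - penalty


def family_score(
    dataset: UniversalDataset,
    child: str,
    parents: list[str] | tuple[str, ...] = (),
    max_parents: int | None = None,
) -> float:
    """Decomposable family score of one node given its parent set."""
    y = dataset.column(child)
    if parents:
        P = np.column_stack([dataset.column(p) for p in parents])
    else:
        P = None
    return _family_score_arrays(y, P, max_parents)


# ---------------------------------------------------------------------------
# structure search


class _Search:
    """One hill-climbing run over add/delete/reverse moves with a score cache."""

    def __init__(self, X: np.ndarray, labels: list[str], max_parents: int):
        self.X = X
        self.labels = labels
        self.p = len(labels)
        self.max_parents = max_parents
        self.cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def fs(self, child: int, parents: tuple[int, ...]) -> float:
        key = (child, parents)
        if key not in self.cache:
            P = self.X[:, list(parents)] if parents else None
            self.cache[key] = _family_score_arrays(self.X[:, child], P)
        return self.cache[key]

    def climb(self, parent_sets: list[set[int]]) -> tuple[list[set[int]], float]:
        p = self.p
        scores = [self.fs(v, tuple(sorted(parent_sets[v]))) for v in range(p)]
        children: list[set[int]] = [set() for _ in range(p)]
        for v in range(p):
            for u in parent_sets[v]:
                children[u].add(v)

        def creates_cycle(u: int, v: int, extra_removed: tuple[int, int] | None = None) -> bool:
            # would u -> v close a cycle? i.e. is u reachable from v
            stack, seen = [v], {v}
            while stack:
                w = stack.pop()
                if w == u:
                    return True
                for x in children[w]:
                    if extra_removed is not None and (w, x) == extra_removed:
                        continue
                    if x not in seen:
                        seen.add(x)
                        stack.append(x)
            return False

        while True:
            best_delta, best_move = _EPS, None
            for u in range(p):
                for v in range(p):
                    if u == v:
                        continue
                    if u in parent_sets[v]:
                        # delete u -> v
                        new = tuple(sorted(parent_sets[v] - {u}))
                        delta = self.fs(v, new) - scores[v]
                        if delta > best_delta:
                            best_delta, best_move = delta, ("del", u, v)
                        # reverse u -> v  (becomes v -> u)
                        if len(parent_sets[u]) < self.max_parents and not creates_cycle(
                            v, u, extra_removed=(u, v)
                        ):
                            new_u = tuple(sorted(parent_sets[u] | {v}))
                            delta = (
                                self.fs(v, new)
                                - scores[v]
                                + self.fs(u, new_u)
                                - scores[u]
                            )
                            if delta > best_delta:
                                best_delta, best_move = delta, ("rev", u, v)
                    elif v not in parent_sets[u]:
                        # add u -> v
                        if len(parent_sets[v]) >= self.max_parents or creates_cycle(u, v):
                            continue
                        new = tuple(sorted(parent_sets[v] | {u}))
                        delta = self.fs(v, new) - scores[v]
                        if delta > best_delta:
                            best_delta, best_move = delta, ("add", u, v)
            if best_move is None:
                break
            kind, u, v = best_move
            if kind == "add":
                parent_sets[v].add(u)
                children[u].add(v)
            elif kind == "del":
                parent_sets[v].discard(u)
                children[u].discard(v)
            else:
                parent_sets[v].discard(u)
                children[u].discard(v)
                parent_sets[u].add(v)
                children[v].add(u)
                scores[u] = self.fs(u, tuple(sorted(parent_sets[u])))
            scores[v] = self.fs(v, tuple(sorted(parent_sets[v])))
        return parent_sets, float(sum(scores))


def learn_structure(
    dataset: UniversalDataset,
    max_parents: int = DEFAULT_MAX_PARENTS,
    restarts: int = 2,
    seed: int = 0,
    strict: bool = False,
) -> UniversalGraph:
    """Greedy hill-climbing structure search with seeded random restarts.

    Restart 0 starts from the empty graph; each further restart starts from
    a sparse random DAG drawn from ``seed``.  The best-scoring local optimum
    is returned.  Constant columns carry no information: in strict mode they
    are an error, otherwise they are dropped with a warning.  Deterministic
    given (dataset, seed): candidate moves are scanned in a fixed label
    order, so equal-score ties always resolve the same way.
    """
    import warnings

    if dataset.values.shape[1] < 2:
        raise ValueError("structure learning needs at least two contacts")
    labels = list(dataset.contact_labels)
    X = dataset.values
    col_sums = X.sum(axis=0)
    constant = (col_sums == 0) | (col_sums == X.shape[0])
    if constant.any():
        bad = [lab for lab, c in zip(labels, constant) if c]
        if strict:
            raise ValueError(f"constant columns present: {bad}")
        warnings.warn(f"dropping constant columns: {bad}", stacklevel=2)
        keep = ~constant
        X = X[:, keep]
        labels = [lab for lab, k in zip(labels, keep) if k]
    # canonical node order: sorted labels, so results do not depend on input order
    order = np.argsort(labels)
    labels_sorted = [labels[i] for i in order]
    X = X[:, order]
    p = len(labels_sorted)

    search = _Search(X, labels_sorted, max_parents)
    rng = np.random.default_rng(seed)
    best_sets: list[set[int]] | None = None
    best_score = -np.inf
    for r in range(max(1, restarts + 1)):
        if r == 0:
            start: list[set[int]] = [set() for _ in range(p)]
        else:
            # random DAG: random topological order, sparse random parents
            perm = rng.permutation(p)
            pos = np.empty(p, dtype=int)
            pos[perm] = np.arange(p)
            start = [set() for _ in range(p)]
            for v in range(p):
                earlier = [u for u in range(p) if pos[u] < pos[v]]
                if earlier:
                    k = int(rng.integers(0, min(max_parents, len(earlier)) + 1))
                    start[v] = set(rng.choice(earlier, size=k, replace=False).tolist())
        sets_r, score_r = search.climb(start)
        if score_r > best_score + _EPS:
            best_score, best_sets = score_r, [set(s) for s in sets_r]
    assert best_sets is not None
    edges = {
        (labels_sorted[u], labels_sorted[v])
        for v in range(p)
        for u in best_sets[v]
    }
    node_score = {
        labels_sorted[v]: search.fs(v, tuple(sorted(best_sets[v]))) for v in range(p)
    }
    return UniversalGraph(labels_sorted, edges, node_score=node_score)


def edge_strengths(graph: UniversalGraph, dataset: UniversalDataset) -> UniversalGraph:
    """Annotate every edge with the plug-in MI (bits) of its endpoints."""
    for parent, child in graph.edges:
        graph.edge_strength[(parent, child)] = pairwise_mi(
            dataset.column(parent), dataset.column(child)
        )
    return graph


def weighted_degree(graph: UniversalGraph) -> dict[str, float]:
    """D_i = sum of incident edge strengths, direction ignored."""
    if graph.edges and not graph.edge_strength:
        raise ValueError("edge strengths not computed; call edge_strengths first")
    degree = {n: 0.0 for n in graph.nodes}
    for (p, c), s in graph.edge_strength.items():
        degree[p] += s
        degree[c] += s
    return degree
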