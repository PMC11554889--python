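"""Brute-force reference implementations used to cross-check the package.

Every oracle here is written in the most literal way possible (explicit
loops, exhaustive enumeration) so that agreement with the vectorized
production code is meaningful evidence of correctness.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------- variance

def variance_oracle(row: np.ndarray) -> float:
    """Two-pass unbiased sample variance."""
    n = len(row)
    mean = sum(row) / n
    return sum((x - mean) ** 2 for x in row) / (n - 1)


# ------------------------------------------------------------- correlation

def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    return num / (dx * dy)


def adjacency_oracle(values: np.ndarray, beta: float) -> np.ndarray:
    """|Pearson|^beta by explicit double loop, unit diagonal."""
    g = values.shape[0]
    a = np.empty((g, g))
    for i in range(g):
        for j in range(g):
            a[i, j] = 1.0 if i == j else abs(pearson_oracle(values[i], values[j])) ** beta
    return a


def tom_oracle(adj: np.ndarray) -> np.ndarray:
    """Unsigned TOM by explicit triple loop."""
    n = adj.shape[0]
    tom = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            l_ij = sum(adj[i, u] * adj[u, j] for u in range(n) if u != i and u != j)
            k_i = sum(adj[i, u] for u in range(n) if u != i)
            k_j = sum(adj[j, u] for u in range(n) if u != j)
            denom = min(k_i, k_j) + 1.0 - adj[i, j]
            tom[i, j] = 0.0 if denom <= 0 else (l_ij + adj[i, j]) / denom
    return tom


# ------------------------------------------------------------------ graphs

def _components(nodes, edge_set):
    """Connected components by repeated flood fill."""
    nodes = list(nodes)
    unseen = set(nodes)
    comps = []
    while unseen:
        start = unseen.pop()
        comp = {start}
        frontier = [start]
        while frontier:
            v = frontier.pop()
            for w in list(unseen):
                if (v, w) in edge_set or (w, v) in edge_set:
                    unseen.discard(w)
                    comp.add(w)
                    frontier.append(w)
        comps.append(comp)
    return comps


def shortest_paths_oracle(nodes, edge_set, source):
    """BFS distances from source (unweighted)."""
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for v in frontier:
            for w in nodes:
                if w in dist:
                    continue
                if (v, w) in edge_set or (w, v) in edge_set:
                    dist[w] = dist[v] + 1
                    nxt.append(w)
        frontier = nxt
    return dist


def harmonic_closeness_oracle(nodes, edge_set, v) -> float:
    dist = shortest_paths_oracle(nodes, edge_set, v)
    return sum(1.0 / d for w, d in dist.items() if w != v)


def degree_oracle(nodes, edge_set, v) -> int:
    return sum(
        1 for w in nodes if w != v and ((v, w) in edge_set or (w, v) in edge_set)
    )


def mnc_dmnc_oracle(nodes, edge_set, v, epsilon: float = 1.7):
    """(MNC, DMNC) via explicit neighborhood-subgraph component search."""
    nbrs = [w for w in nodes if w != v and ((v, w) in edge_set or (w, v) in edge_set)]
    if not nbrs:
        return 0, 0.0
    sub_edges = {
        (a, b) for a, b in itertools.combinations(nbrs, 2)
        if (a, b) in edge_set or (b, a) in edge_set
    }
    comps = _components(nbrs, sub_edges)
    largest = max(comps, key=len)
    n_edges = sum(1 for a, b in sub_edges if a in largest and b in largest)
    return len(largest), (n_edges / len(largest) ** epsilon if largest else 0.0)


def maximal_cliques_oracle(nodes, edge_set):
    """All maximal cliques by exhaustive subset enumeration (small graphs)."""
    nodes = list(nodes)

    def is_clique(sub):
        return all(
            (a, b) in edge_set or (b, a) in edge_set
            for a, b in itertools.combinations(sub, 2)
        )

    cliques = []
    for r in range(1, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if is_clique(sub):
                cliques.append(set(sub))
    return [c for c in cliques if not any(c < d for d in cliques)]


def mcc_oracle(nodes, edge_set, v) -> int:
    """MCC by exhaustive maximal-clique enumeration; isolated nodes score 0."""
    if degree_oracle(nodes, edge_set, v) == 0:
        return 0
    total = 0
    for c in maximal_cliques_oracle(nodes, edge_set):
        if v in c and len(c) >= 2:
            total += math.factorial(len(c) - 1)
    return total


def component_size_oracle(nodes, edge_set, v) -> int:
    for comp in _components(nodes, edge_set):
        if v in comp:
            return len(comp)
    raise KeyError(v)


# ------------------------------------------------------------------ screen

def acc_at_fpr_oracle(scores, labels, fpr_level: float = 0.10) -> float:
    """Exhaustive threshold enumeration: positive iff score >= t."""
    scores = list(map(float, scores))
    labels = list(map(int, labels))
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    candidates = sorted(set(scores)) + [float("inf")]
    best = None  # (tpr, threshold, acc)
    for t in candidates:
        pred = [s >= t for s in scores]
        fp = sum(1 for p, y in zip(pred, labels) if p and y == 0)
        if fp / n_neg > fpr_level:
            continue
        tp = sum(1 for p, y in zip(pred, labels) if p and y == 1)
        correct = sum(1 for p, y in zip(pred, labels) if p == bool(y))
        key = (tp / n_pos, t)
        if best is None or key > (best[0], best[1]):
            best = (tp / n_pos, t, correct / len(labels))
    return best[2]


def random_graph(rng, n_nodes: int, p: float):
    """(nodes, edge_set) Erdos-Renyi graph with string node ids."""
    nodes = [f"n{i}" for i in range(n_nodes)]
    edge_set = {
        (a, b)
        for a, b in itertools.combinations(nodes, 2)
        if rng.random() < p
    }
    return nodes, edge_set
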