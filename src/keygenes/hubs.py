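"""Topological hub-gene analysis on protein-protein interaction networks.

Six node measures drive hub selection: degree, harmonic closeness, the size
(MNC) and density (DMNC) of the largest connected component of a node's
neighborhood subgraph, maximal clique centrality (MCC, the sum of
(|C| - 1)! over maximal cliques through the node), and the edge-percolated
component (EPC, the expected number of nodes reachable under random edge
percolation). Per-measure descending ranks are averaged into one aggregate
rank; dense complexes are extracted with the MCODE seeded-greedy procedure.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("keygenes")


@dataclass
class InteractionNetwork:
    """Undirected interaction network with optional confidence weights in [0,1].

    Self-loops are dropped on construction; parallel edges collapse to the
    maximum weight seen.
    """

    graph: nx.Graph

    @classmethod
    def from_edges(cls, nodes, edges) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for item in edges:
            a, b = item[0], item[1]
            w = float(item[2]) if len(item) > 2 else 1.0
            if a == b:
                continue
            if g.has_edge(a, b):
                g[a][b]["weight"] = max(g[a][b]["weight"], w)
            else:
                g.add_edge(a, b, weight=w)
        return cls(g)

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def subgraph(self, nodes) -> "InteractionNetwork":
        return InteractionNetwork(self.graph.subgraph(nodes).copy())

    def edge_frame(self) -> pd.DataFrame:
        rows = [(a, b, d.get("weight", 1.0)) for a, b, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["node1", "node2", "combined_score"])


def read_edge_list(path: str | Path, score_cutoff: float = 0.4) -> InteractionNetwork:
    """Parse a STRING-style TSV edge list (node1, node2[, combined_score]).

    Scores on the 0-1000 STRING scale are normalized to [0,1]; edges below
    ``score_cutoff`` are dropped, self-loops removed, duplicates collapsed
    to the maximum score.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty edge list: {path}")
    rows = []
    header_tokens = {"node1", "node2", "protein1", "protein2", "combined_score", "score"}
    start = 1 if set(lines[0].lower().replace(",", "\t").split("\t")) & header_tokens else 0
    for ln in lines[start:]:
        parts = ln.split("\t") if "\t" in ln else ln.split()
        if len(parts) < 2:
            raise ValueError(f"malformed edge row: {ln!r}")
        a, b = parts[0], parts[1]
        if len(parts) >= 3:
            try:
                w = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"malformed score in row: {ln!r}") from exc
        else:
            w = 1.0
        rows.append((a, b, w))
    scores = np.array([r[2] for r in rows])
    if scores.size and scores.max() > 1.0:  # STRING 0-1000 convention
        rows = [(a, b, w / 1000.0) for a, b, w in rows]
    rows = [(a, b, w) for a, b, w in rows if w >= score_cutoff and a != b]
    nodes = sorted({n for a, b, _ in rows for n in (a, b)})
    return InteractionNetwork.from_edges(nodes, rows)


def write_edge_list(net: InteractionNetwork, path: str | Path) -> None:
    net.edge_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- measures

def degree_scores(net: InteractionNetwork) -> dict:
    return dict(net.graph.degree())


def closeness_scores(net: InteractionNetwork) -> dict:
    """Harmonic closeness sum_{w != v} 1/d(v, w); finite on disconnected graphs."""
    return nx.harmonic_centrality(net.graph)


def _neighborhood_component(graph: nx.Graph, v):
    nbrs = list(graph.neighbors(v))
    if not nbrs:
        return None
    h = graph.subgraph(nbrs)
    comps = list(nx.connected_components(h))
    largest = max(comps, key=lambda c: (len(c), sorted(c)[0] if c else ""))
    return h.subgraph(largest)


def mnc(net: InteractionNetwork, v) -> int:
    """Maximum neighborhood component: node count of the largest connected
    component of the subgraph induced on v's neighbors (v excluded)."""
    comp = _neighborhood_component(net.graph, v)
    return 0 if comp is None else comp.number_of_nodes()


def dmnc(net: InteractionNetwork, v, epsilon: float = 1.7) -> float:
    """Density of the maximum neighborhood component: |E(C)| / |V(C)|**epsilon."""
    comp = _neighborhood_component(net.graph, v)
    if comp is None or comp.number_of_nodes() == 0:
        return 0.0
    return comp.number_of_edges() / comp.number_of_nodes() ** epsilon


def mcc_scores(net: InteractionNetwork, clique_budget: int = 2_000_000) -> dict:
    """Maximal clique centrality for every node.

    MCC(v) = sum over maximal cliques C containing v of (|C| - 1)!; an
    isolated node scores 0. Cliques come from Bron-Kerbosch with pivoting;
    graphs producing more than ``clique_budget`` cliques are refused.
    """
    scores = {v: 0 for v in net.graph.nodes}
    count = 0
    for clique in nx.find_cliques(net.graph):
        count += 1
        if count > clique_budget:
            raise RuntimeError(f"maximal clique count exceeds budget ({clique_budget})")
        if len(clique) < 2:  # singleton "clique" of an isolated node
            continue
        contrib = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += contrib
    return scores


def mcc(net: InteractionNetwork, v) -> int:
    return mcc_scores(net)[v]


def epc_scores(
    net: InteractionNetwork,
    trials: int = 1000,
    seed: int = 0,
    retention: float | None = None,
) -> dict:
    """Edge-percolated component for every node.

    Each trial draws a global threshold u ~ U(0,1) and i.i.d. edge values;
    edges with value >= u survive. A node's trial score is the size of its
    connected component in the percolated graph (itself included); EPC is
    the mean over trials. ``retention`` overrides the random scheme with a
    fixed per-edge survival probability (0 and 1 are the degenerate checks).
    """
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    nodes = list(net.graph.nodes)
    n = len(nodes)
    if n == 0:
        return {}
    idx = {v: i for i, v in enumerate(nodes)}
    edges = np.array(
        [(idx[a], idx[b]) for a, b in net.graph.edges], dtype=int
    ).reshape(-1, 2)
    m = edges.shape[0]
    rng = np.random.default_rng(seed)
    totals = np.zeros(n)
    for _ in range(trials):
        if m == 0:
            keep = np.zeros(0, dtype=bool)
        elif retention is not None:
            keep = (np.ones(m, dtype=bool) if retention >= 1.0
                    else np.zeros(m, dtype=bool) if retention <= 0.0
                    else rng.random(m) < retention)
        else:
            u = rng.random()
            keep = rng.random(m) >= u
        kept = edges[keep]
        adj = sp.coo_matrix(
            (np.ones(kept.shape[0]), (kept[:, 0], kept[:, 1])), shape=(n, n)
        )
        _, comp = connected_components(adj, directed=False)
        sizes = np.bincount(comp, minlength=comp.max() + 1)
        totals += sizes[comp]
    return {v: totals[idx[v]] / trials for v in nodes}


def epc(net: InteractionNetwork, v, trials: int = 1000, seed: int = 0,
        retention: float | None = None) -> float:
    return epc_scores(net, trials=trials, seed=seed, retention=retention)[v]


# ------------------------------------------------------------- aggregation

MEASURES = ("degree", "closeness", "mnc", "dmnc", "epc", "mcc")


def score_table(
    net: InteractionNetwork,
    epc_trials: int = 1000,
    seed: int = 0,
    dmnc_epsilon: float = 1.7,
    clique_budget: int = 2_000_000,
) -> pd.DataFrame:
    """Per-node table of the six topological measures plus the aggregate rank."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    deg = degree_scores(net)
    clo = closeness_scores(net)
    mcc_ = mcc_scores(net, clique_budget=clique_budget)
    epc_ = epc_scores(net, trials=epc_trials, seed=seed)
    rows = {
        v: (
            deg[v],
            clo[v],
            mnc(net, v),
            dmnc(net, v, epsilon=dmnc_epsilon),
            epc_[v],
            mcc_[v],
        )
        for v in net.graph.nodes
    }
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(MEASURES))
    table.index.name = "node"
    ranks = table.rank(ascending=False, method="average")
    table["agg_rank"] = ranks.mean(axis=1)
    return table.sort_index()


def rank_hubs(table: pd.DataFrame, top_n: int = 10, method: str = "mean_rank") -> list:
    """Order nodes by aggregate rank (ties broken lexicographically by id).

    ``method='top_k_intersection'`` instead returns nodes present in every
    per-measure top-``top_n`` list, ordered by aggregate rank.
    """
    if top_n > len(table):
        warnings.warn(f"top_n={top_n} exceeds node count {len(table)}; returning all")
        top_n = len(table)
    tmp = table.copy()
    tmp["_id"] = tmp.index.astype(str)
    ordered = tmp.sort_values(["agg_rank", "_id"])
    if method == "mean_rank":
        return list(ordered.index[:top_n])
    if method == "top_k_intersection":
        keep = None
        for m in MEASURES:
            top = set(table[m].sort_values(ascending=False).index[:top_n])
            keep = top if keep is None else keep & top
        return [v for v in ordered.index if v in keep]
    raise ValueError(f"unknown aggregation method {method!r}")


# ------------------------------------------------------------------ MCODE

def _mcode_weights(graph: nx.Graph) -> dict:
    weights = {}
    for v in graph.nodes:
        nbhd = list(graph.neighbors(v)) + [v]
        sub = graph.subgraph(nbhd)
        cores = nx.core_number(sub) if sub.number_of_edges() else {u: 0 for u in sub}
        kmax = max(cores.values()) if cores else 0
        if kmax == 0:
            weights[v] = 0.0
            continue
        core_sub = sub.subgraph([u for u, c in cores.items() if c >= kmax])
        nv = core_sub.number_of_nodes()
        density = (2 * core_sub.number_of_edges() / (nv * (nv - 1))) if nv > 1 else 0.0
        weights[v] = kmax * density
    return weights


def mcode_modules(
    net: InteractionNetwork,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
    max_depth: int = 100,
) -> list[tuple[list, float]]:
    """Detect dense complexes with the MCODE seeded-greedy procedure.

    Nodes are weighted by (highest core number of their closed neighborhood)
    x (density of that core). Complexes grow outward from the highest-weight
    unseen seed, admitting neighbors whose weight is within
    ``node_score_cutoff`` of the seed's, up to ``max_depth`` hops. Complexes
    of >= 3 nodes whose induced subgraph contains a ``k_core`` are reported,
    ranked by density x size.
    """
    graph = net.graph
    weights = _mcode_weights(graph)
    seen: set = set()
    complexes = []
    for seed_node in sorted(weights, key=lambda v: (-weights[v], str(v))):
        if seed_node in seen or weights[seed_node] <= 0:
            continue
        threshold = weights[seed_node] * (1 - node_score_cutoff)
        members = {seed_node}
        frontier = [seed_node]
        depth = 0
        while frontier and depth < max_depth:
            nxt = []
            for u in frontier:
                for w in graph.neighbors(u):
                    if w in members or w in seen:
                        continue
                    if weights[w] >= threshold:
                        members.add(w)
                        nxt.append(w)
            frontier = nxt
            depth += 1
        seen |= members
        if len(members) < 3:
            continue
        sub = graph.subgraph(members)
        if max(nx.core_number(sub).values(), default=0) < k_core:
            continue
        nv = sub.number_of_nodes()
        density = 2 * sub.number_of_edges() / (nv * (nv - 1))
        complexes.append((sorted(members, key=str), density * nv))
    complexes.sort(key=lambda cs: (-cs[1], cs[0]))
    return complexes


# ----------------------------------------------------------- model surface

class HubAnalysis:
    """Model-style wrapper: score a network once, query the results.

    Parameters
    ----------
    network : InteractionNetwork
    epc_trials : int
        Monte-Carlo trials for the EPC measure.
    seed : int
        Seed for the EPC percolation draws (the only stochastic measure).
    """

    def __init__(self, network: InteractionNetwork, epc_trials: int = 1000,
                 seed: int = 0, dmnc_epsilon: float = 1.7,
                 clique_budget: int = 2_000_000):
        self.network = network
        self.epc_trials = epc_trials
        self.seed = seed
        self.dmnc_epsilon = dmnc_epsilon
        self.clique_budget = clique_budget

    def fit(self) -> "HubResults":
        table = score_table(
            self.network,
            epc_trials=self.epc_trials,
            seed=self.seed,
            dmnc_epsilon=self.dmnc_epsilon,
            clique_budget=self.clique_budget,
        )
        return HubResults(self, table)


@dataclass
class HubResults:
    model: HubAnalysis
    table: pd.DataFrame

    def top(self, n: int = 10, method: str = "mean_rank") -> list:
        return rank_hubs(self.table, top_n=n, method=method)

    def complexes(self, node_score_cutoff: float = 0.2, k_core: int = 2,
                  max_depth: int = 100) -> list[tuple[list, float]]:
        return mcode_modules(self.model.network, node_score_cutoff, k_core, max_depth)

    def summary(self) -> str:
        net = self.model.network
        lines = [
            "Hub analysis",
            f"  nodes: {net.n_nodes}   edges: {net.n_edges}",
            f"  EPC trials: {self.model.epc_trials} (seed {self.model.seed})",
            "",
            self.table.sort_values("agg_rank").head(10).to_string(
                float_format=lambda x: f"{x:.3f}"
            ),
        ]
        return "\n".join(lines)
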