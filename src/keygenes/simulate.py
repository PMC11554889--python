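"""Synthetic case/control expression data and interaction networks.

The expression generator is a latent-factor model: genes assigned to module
``m`` load on a per-sample standard-normal eigengene series ``e_m`` with

    x_gs = baseline_g + sqrt(rho) * e_m(s) + sqrt(1 - rho) * eps_gs,

``eps ~ N(0, noise_sd^2)``, so that with ``noise_sd = 1`` the within-module
Pearson correlation equals ``rho`` exactly in expectation. Differentially
expressed genes carry an additive group-mean offset of ``delta * noise_sd``:
up-regulated genes have case samples shifted up, down-regulated genes have
control samples shifted up. The two constructions give the same group-mean
difference while keeping both group means positive, so ratio-based fold
changes stay defined and symmetric in sign. Background genes (module 0) are
pure noise around the baseline.

A companion network generator plants hub nodes — a dense clique wired to a
sizeable random slice of the periphery — on top of an Erdos-Renyi background,
giving ground truth for the topological hub measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import ExpressionDataset
from .hubs import InteractionNetwork


@dataclass
class SimulationSpec:
    """Parameters of the expression generator.

    ``module_sizes`` genes belong to correlated modules; a
    ``de_gene_fraction`` of all genes receives a group-mean shift of
    ``de_effect_size * noise_sd`` (half up, half down), planted inside the
    modules first and then in the background. ``baseline`` is a positive
    log-intensity offset shared by all genes.
    """

    n_genes: int = 1000
    n_case: int = 100
    n_control: int = 100
    module_sizes: tuple[int, ...] = (50, 50, 50)
    within_module_correlation: float = 0.8
    de_gene_fraction: float = 0.1
    de_effect_size: float = 2.5
    noise_sd: float = 1.0
    baseline: float = 1.5
    de_in_modules: bool = True
    # "alternate": half up, half down; "up"/"down": one direction;
    # "by_module": odd modules up, even modules down, background alternates
    de_direction: str = "alternate"
    seed: int = 0

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes sum exceeds n_genes")
        if not (0 <= self.within_module_correlation < 1):
            raise ValueError("within_module_correlation must be in [0, 1)")
        if self.de_effect_size < 0 or self.noise_sd <= 0:
            raise ValueError("infeasible effect size / noise level")
        if not (0 <= self.de_gene_fraction <= 1):
            raise ValueError("de_gene_fraction must be in [0, 1]")
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("need at least one sample per group")
        if self.de_direction not in ("alternate", "up", "down", "by_module"):
            raise ValueError(
                "de_direction must be 'alternate', 'up', 'down' or 'by_module'"
            )


@dataclass
class PlantedTruth:
    """Ground truth of a simulation: which genes were shifted (and in which
    direction), the module assignment, the latent eigengene series, and —
    for the network generator — the planted hub ids."""

    de_genes: dict[str, int] = field(default_factory=dict)  # gene id -> +1 / -1
    module_of: dict[str, int] = field(default_factory=dict)  # gene id -> module (0 = background)
    eigengenes: np.ndarray | None = None  # (n_modules, n_samples) latent series
    hub_ids: list[str] = field(default_factory=list)


def simulate_expression(spec: SimulationSpec) -> tuple[ExpressionDataset, PlantedTruth]:
    """Draw one dataset from the factor model; pure function of the seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_case + spec.n_control
    g = spec.n_genes
    rho = spec.within_module_correlation

    gene_ids = [f"G{i:05d}" for i in range(g)]
    sample_ids = [f"S{j:04d}" for j in range(n)]
    labels = np.array([1] * spec.n_case + [0] * spec.n_control)
    case = labels == 1

    module_of = np.zeros(g, dtype=int)
    pos = 0
    for m, size in enumerate(spec.module_sizes, start=1):
        module_of[pos:pos + size] = m
        pos += size

    eig = rng.standard_normal((spec.n_modules, n))
    eps = rng.standard_normal((g, n)) * spec.noise_sd
    values = np.full((g, n), float(spec.baseline)) + np.sqrt(1.0 - rho) * eps
    for m in range(1, spec.n_modules + 1):
        rows = module_of == m
        values[rows] += np.sqrt(rho) * eig[m - 1]
    # background genes are pure noise at full noise_sd
    bg = module_of == 0
    values[bg] = spec.baseline + eps[bg]

    n_de = int(round(spec.de_gene_fraction * g))
    in_modules = np.flatnonzero(module_of > 0)
    in_bg = np.flatnonzero(module_of == 0)
    order = np.concatenate([in_modules, in_bg]) if spec.de_in_modules else np.concatenate([in_bg, in_modules])
    de_rows = order[:n_de]

    shift = spec.de_effect_size * spec.noise_sd
    de_genes: dict[str, int] = {}
    for j, row in enumerate(de_rows):
        if spec.de_direction == "up":
            direction = 1
        elif spec.de_direction == "down":
            direction = -1
        elif spec.de_direction == "by_module" and module_of[row] > 0:
            direction = 1 if module_of[row] % 2 == 1 else -1
        else:
            direction = 1 if j % 2 == 0 else -1
        if direction > 0:
            values[row, case] += shift
        else:
            values[row, ~case] += shift
        de_genes[gene_ids[row]] = direction

    data = ExpressionDataset(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        labels=labels,
        dataset_tags=[f"SIM{spec.seed}"] * n,
    )
    truth = PlantedTruth(
        de_genes=de_genes,
        module_of={gid: int(m) for gid, m in zip(gene_ids, module_of)},
        eigengenes=eig,
    )
    return data, truth


def simulate_network(
    n_nodes: int = 100,
    n_hubs: int = 10,
    clique_size: int = 10,
    background_p: float = 0.02,
    seed: int = 0,
    node_ids: list[str] | None = None,
    hub_fanout_fraction: float = 0.10,
) -> tuple[InteractionNetwork, PlantedTruth]:
    """Erdos-Renyi background with planted hub cliques.

    The first ``n_hubs`` nodes are hubs: they are wired into cliques of
    ``clique_size`` (one clique over all hubs when ``clique_size >= n_hubs``)
    and each hub additionally gains edges to a random ``hub_fanout_fraction``
    of the periphery, which keeps hub degrees far above the background degree
    distribution at default settings.
    """
    if clique_size > n_nodes:
        raise ValueError("clique_size exceeds n_nodes")
    if n_hubs > n_nodes:
        raise ValueError("n_hubs exceeds n_nodes")
    if node_ids is None:
        node_ids = [f"N{i:04d}" for i in range(n_nodes)]
    elif len(node_ids) != n_nodes:
        raise ValueError("node_ids length must equal n_nodes")

    rng = np.random.default_rng(seed)
    edges: set[tuple[int, int]] = set()

    # background
    if background_p > 0:
        iu, ju = np.triu_indices(n_nodes, k=1)
        keep = rng.random(iu.size) < background_p
        edges.update(zip(iu[keep].tolist(), ju[keep].tolist()))

    hubs = list(range(n_hubs))
    # hub cliques
    if n_hubs > 1:
        size = max(2, min(clique_size, n_hubs))
        for start in range(0, n_hubs, size):
            members = hubs[start:start + size]
            if len(members) == 1 and start > 0:
                members = hubs[start - 1:start + 1]
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    edges.add((members[a], members[b]))
    # hub fan-out into the periphery
    periphery = np.arange(n_hubs, n_nodes)
    fanout = int(round(hub_fanout_fraction * max(n_nodes - n_hubs, 0)))
    for h in hubs:
        if periphery.size and fanout:
            targets = rng.choice(periphery, size=min(fanout, periphery.size), replace=False)
            for t in targets:
                edges.add((min(h, int(t)), max(h, int(t))))

    net = InteractionNetwork.from_edges(
        node_ids, [(node_ids[i], node_ids[j], 1.0) for i, j in sorted(edges)]
    )
    truth = PlantedTruth(hub_ids=[node_ids[h] for h in hubs])
    return net, truth
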