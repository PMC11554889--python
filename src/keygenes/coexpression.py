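"""Weighted co-expression network analysis and signature-gene selection.

An unsigned weighted network a_ij = |cor(x_i, x_j)|^beta is built over the
genes, with the soft-threshold power beta chosen as the smallest candidate
whose scale-free topology fit reaches R^2 >= 0.8. Genes are clustered by
average-linkage hierarchical clustering on the topological overlap
dissimilarity 1 - TOM; clusters below the minimum module size fall into the
unassigned label 0, and modules whose eigengenes are closer than the merge
height are fused. Each module is summarized by its eigengene (first
principal component of the standardized module submatrix, unit variance,
sign-oriented along mean module expression). Modules whose eigengene
correlates with the binary trait beyond |r| > 0.6 at p < 0.005 are deemed
trait-associated, and signature genes are the members with module
membership MM = |cor(gene, ME)| >= 0.8 and gene significance
GS = |cor(gene, trait)| >= 0.7.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datasets import ExpressionDataset

logger = logging.getLogger("keygenes")


# ------------------------------------------------------------- network ops

def adjacency(data: ExpressionDataset, genes: list[str], beta: int | float) -> np.ndarray:
    """Unsigned soft-thresholded adjacency a_ij = |Pearson(x_i, x_j)|^beta."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if data.n_samples < 3:
        raise ValueError("need at least 3 samples")
    sub = data.values[data.gene_index(genes)]
    sd = sub.std(axis=1, ddof=1)
    bad = [g for g, s in zip(genes, sd) if s == 0]
    if bad:
        raise ValueError(f"zero-variance gene(s): {bad[:10]}")
    corr = np.corrcoef(sub)
    a = np.abs(corr) ** beta
    np.fill_diagonal(a, 1.0)
    return np.clip(a, 0.0, 1.0)


def pick_soft_threshold(
    data: ExpressionDataset,
    genes: list[str],
    candidates=tuple(range(1, 21)),
    r2_cutoff: float = 0.8,
    n_bins: int = 10,
) -> "SoftThresholdScan":
    """Scan candidate powers for approximate scale-free topology.

    For each power, node connectivities k_i = sum_j a_ij (j != i) are
    binned on log10 k; the signed fit R^2 is the squared correlation of
    log10 p(k) on log10 mean-k per bin, negated when the slope is positive
    (a scale-free degree law requires a falling tail). The chosen power is
    the smallest candidate with signed R^2 >= cutoff, or the maximizer
    with a warning when none qualifies.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least 1 candidate power")
    r2s, mean_ks = [], []
    for b in candidates:
        a = adjacency(data, genes, b)
        k = a.sum(axis=0) - 1.0
        mean_ks.append(float(k.mean()))
        r2s.append(_scale_free_fit(k, n_bins=n_bins))
    chosen = None
    for b, r2 in zip(candidates, r2s):
        if r2 >= r2_cutoff:
            chosen = b
            break
    if chosen is None:
        chosen = candidates[int(np.argmax(r2s))]
        warnings.warn(
            f"no candidate power reached signed R^2 >= {r2_cutoff}; "
            f"falling back to the maximizer beta={chosen}"
        )
    return SoftThresholdScan(
        powers=candidates, r_squared=r2s, mean_connectivity=mean_ks, chosen=chosen
    )


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.allclose(k, k[0]):
        raise ValueError("degenerate connectivity distribution")
    # equal-width bins on the linear connectivity scale, log-log regression
    # across bins (the convention of WGCNA's scale-free fit index)
    edges = np.linspace(k.min(), np.nextafter(k.max(), np.inf), n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return 0.0
    xs, ys = np.array(xs), np.array(ys)
    if np.allclose(xs, xs[0]) or np.allclose(ys, ys[0]):
        return 0.0
    slope = np.polyfit(xs, ys, 1)[0]
    r = np.corrcoef(xs, ys)[0, 1]
    return float(-np.sign(slope) * r * r)


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """Unsigned TOM: TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij),
    with l_ij the shared-neighbor weight sum and unit diagonal."""
    a = np.asarray(adj, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    n = a.shape[0]
    off = a.copy()
    np.fill_diagonal(off, 0.0)
    k = off.sum(axis=0)
    l = off @ off  # l_ij = sum_{u != i,j} a_iu a_uj since diag(off) = 0
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - off
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + off) / denom
    tom = np.where(denom <= 0, 0.0, tom)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


# ------------------------------------------------------------ module calls

def detect_modules(
    tom: np.ndarray,
    data: ExpressionDataset | None = None,
    genes: list[str] | None = None,
    min_size: int = 30,
    merge_height: float = 0.1,
    cut_height: float = 0.99,
) -> np.ndarray:
    """Assign genes to modules from the TOM (0 = unassigned).

    Average-linkage clustering of the 1 - TOM dissimilarity is cut at a
    static ``cut_height``; clusters below ``min_size`` become label 0, and
    modules whose eigengene dissimilarity (1 - cor) falls below
    ``merge_height`` are merged iteratively until stable. Eigengene merging
    needs the expression data; without it merging is skipped with a warning.
    Labels are 1..K by decreasing module size.
    """
    d = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(d, 0.0)
    n = d.shape[0]
    if n == 1:
        return np.zeros(1, dtype=int)
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    labels = _enforce_min_size(raw, min_size)

    if merge_height > 0 and labels.max() > 1:
        if data is None or genes is None:
            warnings.warn("no expression data supplied; skipping eigengene merge")
        else:
            labels = _merge_close_modules(data, genes, labels, merge_height)
    return _relabel_by_size(labels)


def _enforce_min_size(raw: np.ndarray, min_size: int) -> np.ndarray:
    labels = np.zeros_like(raw)
    nxt = 1
    for lab, cnt in zip(*np.unique(raw, return_counts=True)):
        if cnt >= min_size:
            labels[raw == lab] = nxt
            nxt += 1
    return labels


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    out = np.zeros_like(labels)
    mods, counts = np.unique(labels[labels > 0], return_counts=True)
    order = mods[np.argsort(-counts, kind="stable")]
    for new, old in enumerate(order, start=1):
        out[labels == old] = new
    return out


def _merge_close_modules(
    data: ExpressionDataset, genes: list[str], labels: np.ndarray, merge_height: float
) -> np.ndarray:
    labels = labels.copy()
    genes = np.asarray(genes)
    while True:
        mods = [m for m in np.unique(labels) if m > 0]
        if len(mods) < 2:
            break
        mes = {m: module_eigengene(data, list(genes[labels == m])) for m in mods}
        best, best_diss = None, merge_height
        for i, m1 in enumerate(mods):
            for m2 in mods[i + 1:]:
                diss = 1.0 - abs(np.corrcoef(mes[m1], mes[m2])[0, 1])
                if diss < best_diss:
                    best, best_diss = (m1, m2), diss
        if best is None:
            break
        labels[labels == best[1]] = best[0]
    return labels


def module_eigengene(data: ExpressionDataset, module_genes: list[str]) -> np.ndarray:
    """First principal component of the gene-standardized module submatrix,
    unit variance, oriented positively along mean module expression."""
    if not module_genes:
        raise ValueError("empty module")
    sub = data.values[data.gene_index(module_genes)]
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - mu) / sd
    # PC1 across samples of the genes x samples matrix
    _, _, vt = np.linalg.svd(z - z.mean(axis=1, keepdims=True), full_matrices=False)
    me = vt[0]
    me = me / me.std(ddof=1)
    mean_profile = z.mean(axis=0)
    if mean_profile.std() > 0 and np.corrcoef(me, mean_profile)[0, 1] < 0:
        me = -me
    return me


def module_trait(eigengenes: dict[int, np.ndarray], labels: np.ndarray) -> pd.DataFrame:
    """Pearson correlation of each eigengene with the 0/1 trait and the
    two-sided p-value from t = r sqrt((n-2)/(1-r^2)) on n-2 df."""
    labels = np.asarray(labels, dtype=float)
    if labels.std() == 0:
        raise ValueError("constant trait")
    n = labels.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    rows = {}
    for m, me in eigengenes.items():
        r = float(np.corrcoef(me, labels)[0, 1])
        rows[m] = (r, _corr_pvalue(r, n))
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["r", "p"])
    out.index.name = "module"
    return out


def _corr_pvalue(r: float, n: int) -> float:
    r = min(max(r, -1.0), 1.0)
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def select_significant_modules(
    trait_table: pd.DataFrame, r_cutoff: float = 0.6, p_cutoff: float = 0.005
) -> list[int]:
    keep = trait_table[(trait_table["r"].abs() > r_cutoff) & (trait_table["p"] < p_cutoff)]
    return list(keep.index)


# ----------------------------------------------------------- model surface

@dataclass
class SoftThresholdScan:
    powers: list[int]
    r_squared: list[float]
    mean_connectivity: list[float]
    chosen: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "power": self.powers,
                "signed_r2": self.r_squared,
                "mean_k": self.mean_connectivity,
                "chosen": [int(b == self.chosen) for b in self.powers],
            }
        )


class CoexpressionAnalysis:
    """Co-expression network model of a (filtered) expression dataset.

    Parameters mirror the published workflow: soft power chosen on the
    scale-free criterion unless given explicitly, minimum module size 30,
    static dendrogram cut, eigengene merge height 0.1.
    """

    def __init__(
        self,
        data: ExpressionDataset,
        genes: list[str] | None = None,
        power: int | None = None,
        power_grid=tuple(range(1, 21)),
        r2_cutoff: float = 0.8,
        min_module_size: int = 30,
        cut_height: float = 0.99,
        merge_height: float = 0.1,
        trait_r_cutoff: float = 0.6,
        trait_p_cutoff: float = 0.005,
        mm_cutoff: float = 0.8,
        gs_cutoff: float = 0.7,
    ):
        self.data = data
        self.genes = list(genes) if genes is not None else list(data.gene_ids)
        self.power = power
        self.power_grid = power_grid
        self.r2_cutoff = r2_cutoff
        self.min_module_size = min_module_size
        self.cut_height = cut_height
        self.merge_height = merge_height
        self.trait_r_cutoff = trait_r_cutoff
        self.trait_p_cutoff = trait_p_cutoff
        self.mm_cutoff = mm_cutoff
        self.gs_cutoff = gs_cutoff

    def fit(self) -> "CoexpressionResults":
        scan = None
        power = self.power
        if power is None:
            scan = pick_soft_threshold(
                self.data, self.genes, self.power_grid, self.r2_cutoff
            )
            power = scan.chosen
        adj = adjacency(self.data, self.genes, power)
        tom = topological_overlap(adj)
        labels = detect_modules(
            tom,
            data=self.data,
            genes=self.genes,
            min_size=self.min_module_size,
            merge_height=self.merge_height,
            cut_height=self.cut_height,
        )
        genes_arr = np.asarray(self.genes)
        mods = [m for m in np.unique(labels) if m > 0]
        eig = {m: module_eigengene(self.data, list(genes_arr[labels == m])) for m in mods}
        trait = (
            module_trait(eig, self.data.labels)
            if mods
            else pd.DataFrame(columns=["r", "p"])
        )

        sub = self.data.values[self.data.gene_index(self.genes)]
        zsub = _standardize_rows(sub)
        mm = pd.DataFrame(index=self.genes, columns=mods, dtype=float)
        for m in mods:
            mez = (eig[m] - eig[m].mean()) / eig[m].std()
            mm[m] = np.abs(zsub @ mez / zsub.shape[1])
        lab = np.asarray(self.data.labels, dtype=float)
        labz = (lab - lab.mean()) / lab.std()
        gs = pd.Series(np.abs(zsub @ labz / zsub.shape[1]), index=self.genes, name="gs")

        return CoexpressionResults(
            model=self, power=power, scan=scan, module_labels=labels,
            eigengenes=eig, trait_table=trait, mm=mm, gs=gs,
        )


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


@dataclass
class CoexpressionResults:
    model: CoexpressionAnalysis
    power: int
    scan: SoftThresholdScan | None
    module_labels: np.ndarray          # aligned with model.genes; 0 = unassigned
    eigengenes: dict[int, np.ndarray]
    trait_table: pd.DataFrame
    mm: pd.DataFrame                   # genes x modules |cor(gene, ME)|
    gs: pd.Series                      # genes |cor(gene, trait)|

    def modules_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.model.genes, "module": self.module_labels})

    def significant_modules(self) -> list[int]:
        if self.trait_table.empty:
            return []
        return select_significant_modules(
            self.trait_table, self.model.trait_r_cutoff, self.model.trait_p_cutoff
        )

    def signature_genes(
        self, mm_cutoff: float | None = None, gs_cutoff: float | None = None
    ) -> list[str]:
        """Genes of trait-associated modules with MM >= mm_cutoff (their own
        module) and GS >= gs_cutoff; union over modules, original order."""
        mm_cut = self.model.mm_cutoff if mm_cutoff is None else mm_cutoff
        gs_cut = self.model.gs_cutoff if gs_cutoff is None else gs_cutoff
        sig_mods = set(self.significant_modules())
        out = []
        for gene, mod in zip(self.model.genes, self.module_labels):
            if mod in sig_mods and self.mm.loc[gene, mod] >= mm_cut and self.gs[gene] >= gs_cut:
                out.append(gene)
        return out

    def summary(self) -> str:
        sizes = pd.Series(self.module_labels).value_counts().sort_index()
        sig = self.significant_modules()
        lines = [
            "Weighted co-expression analysis",
            f"  genes: {len(self.model.genes)}   samples: {self.model.data.n_samples}",
            f"  soft power: {self.power}"
            + (f" (smallest with signed R^2 >= {self.model.r2_cutoff})" if self.scan else " (fixed)"),
            f"  modules: {int((sizes.index > 0).sum())} "
            f"(+{int(sizes.get(0, 0))} unassigned genes)",
            f"  trait-associated modules (|r| > {self.model.trait_r_cutoff}, "
            f"p < {self.model.trait_p_cutoff}): {sig}",
            f"  signature genes (MM >= {self.model.mm_cutoff}, GS >= {self.model.gs_cutoff}): "
            f"{len(self.signature_genes())}",
        ]
        if not self.trait_table.empty:
            lines += ["", self.trait_table.to_string(float_format=lambda x: f"{x:.4g}")]
        return "\n".join(lines)
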