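"""Expression-data containers and tabular I/O.

The on-disk convention is plain TSV: an expression matrix with a header row
of sample ids and a first column of gene ids (genes are rows, log-scale
intensities), plus a sample table with columns ``sample_id``, ``label``
(``case``/``control`` or 1/0) and ``dataset_tag``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("keygenes")

_LABEL_MAP = {"case": 1, "control": 0, "1": 1, "0": 0, 1: 1, 0: 0}


@dataclass
class ExpressionDataset:
    """A genes x samples log-expression matrix with binary phenotype labels.

    Attributes
    ----------
    gene_ids : list of str
        Unique gene identifiers, one per row of ``values``.
    sample_ids : list of str
        Unique sample identifiers, one per column of ``values``.
    values : ndarray, shape (n_genes, n_samples)
        Log-scale expression intensities.
    labels : ndarray of int
        Per-sample phenotype, case=1 / control=0.
    dataset_tags : list of str
        Per-sample origin identifier (e.g. an accession string).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: np.ndarray
    dataset_tags: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n_g, n_s = len(self.gene_ids), len(self.sample_ids)
        if self.values.shape != (n_g, n_s):
            raise ValueError(
                f"matrix shape {self.values.shape} != (genes, samples) = {(n_g, n_s)}"
            )
        if len(self.labels) != n_s:
            raise ValueError("labels length does not match sample count")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (case=1, control=0)")
        if len(self.dataset_tags) != n_s:
            raise ValueError("dataset_tags length does not match sample count")
        if len(set(self.gene_ids)) != n_g:
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != n_s:
            raise ValueError("duplicate sample ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_ids) -> np.ndarray:
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in idx]
        if missing:
            raise KeyError(f"genes not in dataset: {missing[:10]}")
        return np.array([idx[g] for g in gene_ids], dtype=int)

    def subset_genes(self, gene_ids) -> "ExpressionDataset":
        rows = self.gene_index(gene_ids)
        return ExpressionDataset(
            gene_ids=list(gene_ids),
            sample_ids=list(self.sample_ids),
            values=self.values[rows],
            labels=self.labels.copy(),
            dataset_tags=list(self.dataset_tags),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def sample_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "label": ["case" if l else "control" for l in self.labels],
                "dataset_tag": self.dataset_tags,
            }
        )


def read_expression(matrix_path: str | Path, samples_path: str | Path) -> ExpressionDataset:
    """Load an expression TSV and its sample table into a validated dataset.

    Duplicate gene ids are collapsed to their per-gene mean. Samples present
    in the matrix but absent from the table raise an error.
    """
    matrix_path, samples_path = Path(matrix_path), Path(samples_path)
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if mat.empty:
        raise ValueError(f"empty expression matrix: {matrix_path}")
    try:
        mat = mat.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {matrix_path}: {exc}") from exc

    if mat.index.has_duplicates:
        n_dup = int(mat.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene ids by mean", n_dup)
        mat = mat.groupby(level=0, sort=False).mean()

    tab = pd.read_csv(samples_path, sep="\t", dtype=str)
    required = {"sample_id", "label"}
    if not required.issubset(tab.columns):
        raise ValueError(f"sample table needs columns {sorted(required)}")
    if "dataset_tag" not in tab.columns:
        tab["dataset_tag"] = samples_path.stem
    tab = tab.set_index("sample_id")
    if tab.index.has_duplicates:
        raise ValueError("duplicate sample ids in sample table")

    unmapped = [s for s in mat.columns if s not in tab.index]
    if unmapped:
        raise ValueError(f"unmapped sample(s) in matrix: {unmapped}")

    labels = []
    for s in mat.columns:
        raw = tab.loc[s, "label"]
        if raw not in _LABEL_MAP:
            raise ValueError(f"label for sample {s!r} must be case/control or 1/0, got {raw!r}")
        labels.append(_LABEL_MAP[raw])

    return ExpressionDataset(
        gene_ids=list(mat.index),
        sample_ids=list(mat.columns),
        values=mat.to_numpy(),
        labels=np.array(labels, dtype=int),
        dataset_tags=[str(tab.loc[s, "dataset_tag"]) for s in mat.columns],
    )


def write_expression(data: ExpressionDataset, matrix_path: str | Path,
                     samples_path: str | Path) -> None:
    data.to_frame().to_csv(matrix_path, sep="\t")
    data.sample_table().to_csv(samples_path, sep="\t", index=False)


def pool_datasets(datasets: list[ExpressionDataset], zscale: bool = True) -> ExpressionDataset:
    """Concatenate samples across datasets on the intersection of gene ids.

    With ``zscale`` (default) each dataset's rows are z-scored per gene
    before concatenation, a minimal guard against platform-specific location
    and scale when pooling arrays from heterogeneous sources. The pooled
    sample count is exactly the sum of the input counts.
    """
    if len(datasets) < 2:
        raise ValueError("pooling requires at least 2 datasets")
    common = list(datasets[0].gene_ids)
    seen = [set(d.gene_ids) for d in datasets[1:]]
    common = [g for g in common if all(g in s for s in seen)]
    if not common:
        raise ValueError("empty gene intersection across datasets")
    lost = sum(d.n_genes for d in datasets) - len(common) * len(datasets)
    if lost:
        logger.info("pooling keeps %d common genes (%d gene rows dropped)", len(common), lost)

    blocks, sample_ids, labels, tags = [], [], [], []
    for k, d in enumerate(datasets):
        sub = d.subset_genes(common)
        vals = sub.values
        if zscale:
            mu = vals.mean(axis=1, keepdims=True)
            sd = vals.std(axis=1, ddof=1, keepdims=True)
            sd[sd == 0] = 1.0
            vals = (vals - mu) / sd
        blocks.append(vals)
        # disambiguate colliding sample ids across datasets
        for s, t in zip(sub.sample_ids, sub.dataset_tags):
            sid = s if s not in sample_ids else f"{t}:{s}#{k}"
            sample_ids.append(sid)
            tags.append(t)
        labels.extend(sub.labels.tolist())

    return ExpressionDataset(
        gene_ids=common,
        sample_ids=sample_ids,
        values=np.hstack(blocks),
        labels=np.array(labels, dtype=int),
        dataset_tags=tags,
    )


def write_gene_list(genes: list[str], path: str | Path) -> None:
    genes = list(genes)
    if len(set(genes)) != len(genes):
        raise ValueError("gene list contains duplicates")
    Path(path).write_text("".join(g + "\n" for g in genes))


def read_gene_list(path: str | Path) -> list[str]:
    return [line for line in Path(path).read_text().splitlines() if line]
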