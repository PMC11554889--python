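"""Per-gene supervised DEG screening with random-forest and SVM models.

Each gene is evaluated as the sole feature of two classifiers trained on a
stratified 60% split and scored on the held-out 40%: the AUC of the test
ROC and the accuracy at the score threshold constrained to a test false
positive rate of at most 0.10. A gene is called up-regulated when
AUC >= 0.85 and ACC >= 0.85 for both models and logFC > 1, down-regulated
when the scores pass and logFC < -1; the fold change is the log2 ratio of
group means (case over control by default; the reversed convention is
available via ``direction='control_over_case'``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .datasets import ExpressionDataset

logger = logging.getLogger("keygenes")


@dataclass
class SplitPlan:
    """A stratified train/test partition shared by every gene's evaluation."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int
    stratified: bool = True

    def __post_init__(self) -> None:
        if set(self.train_idx) & set(self.test_idx):
            raise ValueError("train and test overlap")


def make_split(labels: np.ndarray, train_fraction: float = 0.60, seed: int = 0) -> SplitPlan:
    """Stratified random split keeping both classes in both parts."""
    labels = np.asarray(labels)
    train, test = [], []
    rng = np.random.default_rng(seed)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"need at least 2 samples of class {cls}, got {idx.size}")
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)  # both parts non-empty per class
        train.extend(idx[:n_train].tolist())
        test.extend(idx[n_train:].tolist())
    return SplitPlan(np.sort(np.array(train)), np.sort(np.array(test)), seed=seed)


def acc_at_fpr(scores: np.ndarray, labels: np.ndarray, fpr_level: float = 0.10) -> float:
    """Accuracy at the TPR-maximizing score threshold with FPR <= fpr_level.

    Thresholds are scanned over the observed scores (prediction rule:
    positive iff score >= threshold, plus the all-negative threshold); among
    thresholds meeting the FPR constraint the one with the highest TPR wins,
    ties going to the higher threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present in the test set")
    thresholds = np.concatenate([np.unique(scores), [np.inf]])
    best = None  # (tpr, threshold, acc)
    for t in thresholds:
        pred = scores >= t
        fpr = (pred & ~pos).sum() / n_neg
        if fpr > fpr_level:
            continue
        tpr = (pred & pos).sum() / n_pos
        acc = (pred == pos).mean()
        if best is None or (tpr, t) > (best[0], best[1]):
            best = (tpr, t, acc)
    return float(best[2])


def score_gene(
    values: np.ndarray,
    labels: np.ndarray,
    plan: SplitPlan,
    model: str,
    fpr_level: float = 0.10,
    rf_trees: int = 50,
    rf_max_depth: int | None = 3,
    svm_c: float = 1.0,
    seed: int = 0,
) -> tuple[float, float]:
    """(AUC, ACC-at-FPR) of one gene as the single feature of one model.

    ``model`` is 'rf' (class-1 probability score) or 'svm' (linear-kernel
    decision value). A gene constant on the training part is uninformative:
    it scores AUC 0.5 and the majority-class accuracy, flagged in the log.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    x_tr = values[plan.train_idx].reshape(-1, 1)
    y_tr = labels[plan.train_idx]
    x_te = values[plan.test_idx].reshape(-1, 1)
    y_te = labels[plan.test_idx]

    if np.ptp(x_tr) == 0:
        logger.debug("constant gene on training part; scoring as uninformative")
        majority = max(y_te.mean(), 1 - y_te.mean())
        return 0.5, float(majority)

    if model == "rf":
        clf = RandomForestClassifier(
            n_estimators=rf_trees, max_depth=rf_max_depth, random_state=seed
        )
        clf.fit(x_tr, y_tr)
        scores = clf.predict_proba(x_te)[:, list(clf.classes_).index(1)]
    elif model == "svm":
        clf = SVC(kernel="linear", C=svm_c)
        clf.fit(x_tr, y_tr)
        scores = clf.decision_function(x_te)
    else:
        raise ValueError(f"unknown model {model!r}")

    auc = float(roc_auc_score(y_te, scores))
    acc = acc_at_fpr(scores, y_te, fpr_level=fpr_level)
    return auc, acc


def log_fold_change(
    values: np.ndarray, labels: np.ndarray, direction: str = "case_over_control"
) -> float:
    """log2 ratio of group mean expressions.

    Requires strictly positive group means (expression on a positive
    log-intensity scale). ``direction='control_over_case'`` computes the
    reversed ratio.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    m_case = values[labels == 1].mean()
    m_ctrl = values[labels == 0].mean()
    if m_case <= 0 or m_ctrl <= 0:
        raise ValueError(
            "non-positive group mean; supply intensities pre-shifted to a positive scale"
        )
    if direction == "case_over_control":
        return float(np.log2(m_case / m_ctrl))
    if direction == "control_over_case":
        return float(np.log2(m_ctrl / m_case))
    raise ValueError(f"unknown logFC direction {direction!r}")


@dataclass
class GeneScreenRecord:
    gene_id: str
    auc_rf: float
    acc_rf: float
    auc_svm: float
    acc_svm: float
    logfc: float
    call: str  # "up", "down", "none"


def screen_all(
    data: ExpressionDataset,
    plan: SplitPlan | None = None,
    auc_cutoff: float = 0.85,
    acc_cutoff: float = 0.85,
    logfc_cutoff: float = 1.0,
    fpr_level: float = 0.10,
    train_fraction: float = 0.60,
    logfc_direction: str = "case_over_control",
    logfc_data: ExpressionDataset | None = None,
    rf_trees: int = 50,
    rf_max_depth: int | None = 3,
    svm_c: float = 1.0,
    seed: int = 0,
    per_gene_split: bool = False,
) -> list[GeneScreenRecord]:
    """Screen every gene; one shared split by default.

    ``logfc_data`` supplies unscaled intensities for the fold change when
    ``data`` itself has been z-scored (e.g. after pooling); it must carry the
    same genes and samples.
    """
    if plan is None:
        plan = make_split(data.labels, train_fraction=train_fraction, seed=seed)
    lf_src = data if logfc_data is None else logfc_data
    if lf_src.gene_ids != data.gene_ids or lf_src.n_samples != data.n_samples:
        raise ValueError("logfc_data must match data in genes and samples")

    records = []
    for i, gene in enumerate(data.gene_ids):
        if per_gene_split:
            plan_i = make_split(data.labels, train_fraction, seed=seed + i + 1)
        else:
            plan_i = plan
        vals = data.values[i]
        auc_rf, acc_rf = score_gene(
            vals, data.labels, plan_i, "rf",
            fpr_level=fpr_level, rf_trees=rf_trees, rf_max_depth=rf_max_depth,
            seed=seed,
        )
        auc_svm, acc_svm = score_gene(
            vals, data.labels, plan_i, "svm", fpr_level=fpr_level, svm_c=svm_c,
        )
        lfc = log_fold_change(lf_src.values[i], data.labels, direction=logfc_direction)
        passed = (
            auc_rf >= auc_cutoff and auc_svm >= auc_cutoff
            and acc_rf >= acc_cutoff and acc_svm >= acc_cutoff
        )
        if passed and lfc > logfc_cutoff:
            call = "up"
        elif passed and lfc < -logfc_cutoff:
            call = "down"
        else:
            call = "none"
        records.append(
            GeneScreenRecord(gene, auc_rf, acc_rf, auc_svm, acc_svm, lfc, call)
        )
    return records


def records_frame(records: list[GeneScreenRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.gene_id, r.auc_rf, r.acc_rf, r.auc_svm, r.acc_svm, r.logfc, r.call)
            for r in records
        ],
        columns=["gene_id", "auc_rf", "acc_rf", "auc_svm", "acc_svm", "logfc", "call"],
    )


# ----------------------------------------------------------- model surface

class GeneScreen:
    """Model-style wrapper around the per-gene dual-classifier screen."""

    def __init__(
        self,
        data: ExpressionDataset,
        auc_cutoff: float = 0.85,
        acc_cutoff: float = 0.85,
        logfc_cutoff: float = 1.0,
        fpr_level: float = 0.10,
        train_fraction: float = 0.60,
        logfc_direction: str = "case_over_control",
        logfc_data: ExpressionDataset | None = None,
        rf_trees: int = 50,
        rf_max_depth: int | None = 3,
        svm_c: float = 1.0,
        per_gene_split: bool = False,
    ):
        self.data = data
        self.auc_cutoff = auc_cutoff
        self.acc_cutoff = acc_cutoff
        self.logfc_cutoff = logfc_cutoff
        self.fpr_level = fpr_level
        self.train_fraction = train_fraction
        self.logfc_direction = logfc_direction
        self.logfc_data = logfc_data
        self.rf_trees = rf_trees
        self.rf_max_depth = rf_max_depth
        self.svm_c = svm_c
        self.per_gene_split = per_gene_split

    def fit(self, seed: int = 0) -> "GeneScreenResults":
        records = screen_all(
            self.data,
            auc_cutoff=self.auc_cutoff,
            acc_cutoff=self.acc_cutoff,
            logfc_cutoff=self.logfc_cutoff,
            fpr_level=self.fpr_level,
            train_fraction=self.train_fraction,
            logfc_direction=self.logfc_direction,
            logfc_data=self.logfc_data,
            rf_trees=self.rf_trees,
            rf_max_depth=self.rf_max_depth,
            svm_c=self.svm_c,
            seed=seed,
            per_gene_split=self.per_gene_split,
        )
        return GeneScreenResults(self, records, seed)


@dataclass
class GeneScreenResults:
    model: GeneScreen
    records: list[GeneScreenRecord]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return records_frame(self.records)

    def degs(self) -> list[str]:
        return [r.gene_id for r in self.records if r.call != "none"]

    def up_genes(self) -> list[str]:
        return [r.gene_id for r in self.records if r.call == "up"]

    def down_genes(self) -> list[str]:
        return [r.gene_id for r in self.records if r.call == "down"]

    def summary(self) -> str:
        n_up, n_down = len(self.up_genes()), len(self.down_genes())
        return "\n".join(
            [
                "Per-gene RF/SVM screen",
                f"  genes: {len(self.records)}   samples: {self.model.data.n_samples} "
                f"(train fraction {self.model.train_fraction:g}, seed {self.seed})",
                f"  criteria: AUC >= {self.model.auc_cutoff:g} and ACC >= "
                f"{self.model.acc_cutoff:g} (both models, FPR <= {self.model.fpr_level:g}), "
                f"|logFC| > {self.model.logfc_cutoff:g}",
                f"  calls: {n_up + n_down} DEGs ({n_up} up, {n_down} down)",
            ]
        )

    def volcano_plot(self, model: str = "rf", path=None):
        """ACC vs logFC scatter colored by call; saves to ``path`` if given."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = self.to_frame()
        acc = df[f"acc_{model}"]
        colors = df["call"].map({"up": "tab:red", "down": "tab:blue", "none": "0.7"})
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.scatter(df["logfc"], acc, c=colors, s=8)
        ax.axhline(self.model.acc_cutoff, ls="--", c="k", lw=0.8)
        ax.axvline(self.model.logfc_cutoff, ls="--", c="k", lw=0.8)
        ax.axvline(-self.model.logfc_cutoff, ls="--", c="k", lw=0.8)
        ax.set_xlabel("log2 fold change")
        ax.set_ylabel(f"ACC ({model})")
        if path is not None:
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
        return fig
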