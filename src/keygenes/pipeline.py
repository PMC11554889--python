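"""Stage orchestration: filter -> co-expression -> screen -> intersect ->
hubs -> validate, with a run manifest and plain-TSV artifacts."""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve

from . import __version__
from .config import PipelineConfig, stage_seed
from .coexpression import CoexpressionAnalysis
from .datasets import ExpressionDataset, pool_datasets, write_expression, write_gene_list
from .hubs import HubAnalysis, InteractionNetwork, mcode_modules, write_edge_list
from .screen import GeneScreen, make_split
from .simulate import SimulationSpec, simulate_expression, simulate_network
from .variance import VarianceFilter

logger = logging.getLogger("keygenes")


@dataclass
class IntersectionReport:
    """Venn arithmetic between the supervised and unsupervised DEG sets."""

    supervised: list[str]
    unsupervised: list[str]
    common: list[str]

    @property
    def counts(self) -> tuple[int, int, int]:
        """(supervised-only, common, unsupervised-only)."""
        c = len(self.common)
        return (len(self.supervised) - c, c, len(self.unsupervised) - c)


def intersect_degs(supervised, unsupervised) -> IntersectionReport:
    """Common DEGs of the two routes, preserving the supervised order."""
    sup = list(dict.fromkeys(supervised))
    uns = list(dict.fromkeys(unsupervised))
    uns_set = set(uns)
    common = [g for g in sup if g in uns_set]
    return IntersectionReport(sup, uns, common)


@dataclass
class ValidationReport:
    """Panel-classifier performance on held-out data."""

    auc: float
    tpr: float
    tnr: float
    acc: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray

    def summary(self) -> str:
        return (
            "Panel validation (random forest)\n"
            f"  AUC = {self.auc:.4f}   ACC = {self.acc:.4f}   "
            f"TPR = {self.tpr:.4f}   TNR = {self.tnr:.4f}"
        )


def validate_panel(
    train: ExpressionDataset,
    test: ExpressionDataset,
    panel: list[str],
    seed: int = 0,
    rf_trees: int = 100,
) -> ValidationReport:
    """Fit a random forest on the panel genes of ``train`` and report ROC/AUC,
    TPR, TNR and accuracy (probability threshold 0.5) on ``test``."""
    missing = [g for g in panel if g not in train.gene_ids or g not in test.gene_ids]
    if missing:
        raise ValueError(f"panel gene(s) missing from data: {missing[:10]}")
    x_tr = train.values[train.gene_index(panel)].T
    x_te = test.values[test.gene_index(panel)].T
    y_tr, y_te = train.labels, test.labels
    clf = RandomForestClassifier(n_estimators=rf_trees, random_state=seed)
    clf.fit(x_tr, y_tr)
    prob = clf.predict_proba(x_te)[:, list(clf.classes_).index(1)]
    fpr, tpr, _ = roc_curve(y_te, prob)
    auc = float(roc_auc_score(y_te, prob))
    pred = prob >= 0.5
    pos, neg = y_te == 1, y_te == 0
    report = ValidationReport(
        auc=auc,
        tpr=float((pred & pos).sum() / pos.sum()),
        tnr=float((~pred & neg).sum() / neg.sum()),
        acc=float((pred == (y_te == 1)).mean()),
        roc_fpr=fpr,
        roc_tpr=tpr,
    )
    return report


@dataclass
class DemoSpec:
    """The packaged demo simulation: several datasets of differing
    case/control make-up sharing one gene universe and planted truth, plus an
    interaction network over the genes whose planted hubs are drawn from the
    planted DE genes.

    The defaults plant two fully differential, direction-coherent modules
    (one activated in cases, one suppressed) and one trait-neutral module on
    a background of noise genes; dataset compositions are deliberately
    unbalanced, as pooled case/control collections are in practice."""

    n_genes: int = 600
    dataset_sizes: tuple[tuple[int, int], ...] = ((80, 60), (70, 70), (100, 40))
    module_sizes: tuple[int, ...] = (50, 50, 50)
    rho: float = 0.8
    de_fraction: float = 0.1  # covers the first module (and a sliver of the second)
    delta: float = 3.0
    de_direction: str = "by_module"
    network_nodes: int = 150
    n_hubs: int = 10
    background_p: float = 0.03


def run_all(
    config: PipelineConfig,
    outdir: str | Path,
    datasets: list[ExpressionDataset] | None = None,
    network: InteractionNetwork | None = None,
    simulate: bool = False,
    demo: DemoSpec | None = None,
) -> dict:
    """Run every stage, writing intermediate TSVs and a manifest.

    With ``simulate`` the packaged demo generator supplies the inputs; the
    first dataset doubles as the unsupervised (variance + co-expression)
    input while all datasets are pooled for the supervised screen, and the
    validation stage refits the final panel on a fresh train/test split of
    the pooled data. Returns a dict of in-memory stage results.
    """
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    results: dict = {}

    def _stage(name):
        logger.info("[%7.2fs] stage: %s", time.time() - t0, name)

    truth = None
    if simulate:
        _stage("simulate")
        demo = demo or DemoSpec()
        datasets = []
        for k, (n_case, n_ctrl) in enumerate(demo.dataset_sizes):
            spec = SimulationSpec(
                n_genes=demo.n_genes,
                n_case=n_case,
                n_control=n_ctrl,
                module_sizes=demo.module_sizes,
                within_module_correlation=demo.rho,
                de_gene_fraction=demo.de_fraction,
                de_effect_size=demo.delta,
                de_direction=demo.de_direction,
                seed=stage_seed(seed, f"simulate/{k}"),
            )
            ds, truth_k = simulate_expression(spec)
            ds.dataset_tags = [f"SIMSET{k}"] * ds.n_samples
            ds.sample_ids = [f"D{k}_{s}" for s in ds.sample_ids]
            datasets.append(ds)
            if k == 0:
                truth = truth_k
        de_ids = list(truth.de_genes)
        hub_genes = de_ids[: demo.n_hubs]
        other = [g for g in datasets[0].gene_ids if g not in set(hub_genes)]
        node_ids = hub_genes + other[: demo.network_nodes - len(hub_genes)]
        network, net_truth = simulate_network(
            n_nodes=len(node_ids),
            n_hubs=len(hub_genes),
            clique_size=len(hub_genes),
            background_p=demo.background_p,
            seed=stage_seed(seed, "simulate/network"),
            node_ids=node_ids,
        )
        truth.hub_ids = net_truth.hub_ids
        for k, ds in enumerate(datasets):
            write_expression(ds, outdir / f"sim_expr_{k}.tsv", outdir / f"sim_samples_{k}.tsv")
        write_edge_list(network, outdir / "sim_network.tsv")
        (outdir / "sim_truth.json").write_text(
            json.dumps(
                {
                    "de_genes": truth.de_genes,
                    "module_of": truth.module_of,
                    "hub_ids": truth.hub_ids,
                },
                indent=1,
            )
        )
        results["truth"] = truth

    if not datasets:
        raise ValueError("no input datasets (pass datasets or simulate=True)")

    # ---- unsupervised route: variance filter + co-expression on dataset 0
    _stage("variance filter")
    unsup = datasets[0]
    vres = VarianceFilter(unsup, p_cutoff=config.variance_p_cutoff,
                          method=config.variance_fit_method).fit()
    vres.to_frame().to_csv(outdir / "variance_filter.tsv", sep="\t", index=False)
    filtered = vres.selected_genes()
    logger.info("variance filter kept %d / %d genes", len(filtered), unsup.n_genes)
    results["variance"] = vres

    _stage("coexpression")
    cres = CoexpressionAnalysis(
        unsup,
        genes=filtered,
        power_grid=config.soft_power_grid,
        r2_cutoff=config.scale_free_r2_cutoff,
        min_module_size=config.min_module_size,
        cut_height=config.cut_height,
        merge_height=config.merge_height,
        trait_r_cutoff=config.module_trait_r_cutoff,
        trait_p_cutoff=config.module_trait_p_cutoff,
        mm_cutoff=config.mm_cutoff,
        gs_cutoff=config.gs_cutoff,
    ).fit()
    cres.modules_frame().to_csv(outdir / "modules.tsv", sep="\t", index=False)
    if cres.scan is not None:
        cres.scan.to_frame().to_csv(outdir / "soft_threshold_scan.tsv", sep="\t", index=False)
    unsup_degs = cres.signature_genes()
    write_gene_list(unsup_degs, outdir / "unsupervised_degs.txt")
    logger.info("co-expression signature genes: %d", len(unsup_degs))
    results["coexpression"] = cres

    # ---- supervised route: pool everything, screen per gene
    _stage("pool + screen")
    if len(datasets) >= 2:
        pooled = pool_datasets(datasets, zscale=config.pool_zscale)
        pooled_raw = pool_datasets(datasets, zscale=False) if config.pool_zscale else pooled
    else:
        pooled = pooled_raw = datasets[0]
    screen_model = GeneScreen(
        pooled,
        auc_cutoff=config.auc_cutoff,
        acc_cutoff=config.acc_cutoff,
        logfc_cutoff=config.logfc_cutoff,
        fpr_level=config.fpr_level,
        train_fraction=config.train_fraction,
        logfc_direction=config.logfc_direction,
        logfc_data=pooled_raw,
        rf_trees=config.rf_trees,
        rf_max_depth=config.rf_max_depth,
        svm_c=config.svm_c,
        per_gene_split=config.split_per_gene,
    )
    sres = screen_model.fit(seed=stage_seed(seed, "screen"))
    sres.to_frame().to_csv(outdir / "screen_table.tsv", sep="\t", index=False)
    sup_degs = sres.degs()
    write_gene_list(sup_degs, outdir / "supervised_degs.txt")
    logger.info("supervised DEGs: %d (%d up, %d down)",
                len(sup_degs), len(sres.up_genes()), len(sres.down_genes()))
    results["screen"] = sres

    # ---- intersection
    _stage("intersect")
    report = intersect_degs(sup_degs, unsup_degs)
    write_gene_list(report.common, outdir / "cdegs.txt")
    logger.info("cDEGs: %d (venn %s)", len(report.common), report.counts)
    results["intersection"] = report

    # ---- hub analysis on the network restricted to cDEGs
    hubs_list: list = []
    complexes: list = []
    if network is not None:
        _stage("hubs")
        keep = [n for n in network.nodes if n in set(report.common)]
        if not keep:
            logger.warning("no cDEGs present in the network; skipping hub stage")
        else:
            subnet = network.subgraph(keep)
            hres = HubAnalysis(
                subnet,
                epc_trials=config.epc_trials,
                seed=stage_seed(seed, "epc"),
                dmnc_epsilon=config.dmnc_epsilon,
                clique_budget=config.clique_budget,
            ).fit()
            hres.table.to_csv(outdir / "hub_scores.tsv", sep="\t")
            hubs_list = hres.top(config.hub_top_n, method=config.rank_aggregation)
            write_gene_list(hubs_list, outdir / "key_genes.txt")
            complexes = mcode_modules(
                subnet,
                node_score_cutoff=config.mcode_node_score_cutoff,
                k_core=config.mcode_k_core,
                max_depth=config.mcode_max_depth,
            )
            pd.DataFrame(
                [(i + 1, ";".join(map(str, nodes)), score)
                 for i, (nodes, score) in enumerate(complexes)],
                columns=["complex", "members", "score"],
            ).to_csv(outdir / "mcode_complexes.tsv", sep="\t", index=False)
            logger.info("top-%d hubs: %s", config.hub_top_n, hubs_list)
            results["hubs"] = hres
            results["complexes"] = complexes

    # ---- panel validation on a fresh split of the pooled data
    panel = hubs_list or report.common
    if panel:
        _stage("validate")
        vseed = stage_seed(seed, "validate")
        plan = make_split(pooled.labels, train_fraction=config.train_fraction, seed=vseed)
        tr_ids = [pooled.sample_ids[i] for i in plan.train_idx]
        te_ids = [pooled.sample_ids[i] for i in plan.test_idx]
        train = _subset_samples(pooled, plan.train_idx)
        test = _subset_samples(pooled, plan.test_idx)
        vrep = validate_panel(train, test, panel, seed=vseed, rf_trees=config.rf_trees)
        pd.DataFrame({"fpr": vrep.roc_fpr, "tpr": vrep.roc_tpr}).to_csv(
            outdir / "validation_roc.tsv", sep="\t", index=False
        )
        results["validation"] = vrep
        logger.info("validation: AUC=%.4f ACC=%.4f TPR=%.4f TNR=%.4f",
                    vrep.auc, vrep.acc, vrep.tpr, vrep.tnr)

    manifest = {
        "package": "keygenes",
        "version": __version__,
        "config": config.to_dict(),
        "n_datasets": len(datasets),
        "pooled_samples": pooled.n_samples,
        "counts": {
            "variance_filtered": len(filtered),
            "unsupervised_degs": len(unsup_degs),
            "supervised_degs": len(sup_degs),
            "cdegs": len(report.common),
            "key_genes": len(hubs_list),
            "complexes": len(complexes),
        },
        "key_genes": hubs_list,
        "elapsed_s": round(time.time() - t0, 2),
    }
    if "validation" in results:
        v = results["validation"]
        manifest["validation"] = {"auc": v.auc, "acc": v.acc, "tpr": v.tpr, "tnr": v.tnr}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    results["manifest"] = manifest
    return results


def _subset_samples(data: ExpressionDataset, idx: np.ndarray) -> ExpressionDataset:
    return ExpressionDataset(
        gene_ids=list(data.gene_ids),
        sample_ids=[data.sample_ids[i] for i in idx],
        values=data.values[:, idx],
        labels=data.labels[idx],
        dataset_tags=[data.dataset_tags[i] for i in idx],
    )


def setup_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(getattr(logging, level.upper()))
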