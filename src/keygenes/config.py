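"""Pipeline configuration: every threshold and seed used downstream.

Defaults are the published cutoffs of the workflow this package implements:
variance p < 0.05, scale-free fit R^2 >= 0.8, minimum module size 30,
eigengene merge height 0.1, module-trait |r| > 0.6 with p < 0.005,
MM >= 0.8, GS >= 0.7, 60/40 train/test split, FPR level 0.10,
AUC >= 0.85 and ACC >= 0.85 for both models, |logFC| > 1, top-10 hubs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # variance filter
    variance_p_cutoff: float = 0.05
    variance_fit_method: str = "mom"  # "mom" or "mle" (ML refinement of MoM)

    # co-expression network
    soft_power_grid: tuple[int, ...] = tuple(range(1, 21))
    scale_free_r2_cutoff: float = 0.8
    min_module_size: int = 30
    cut_height: float = 0.99            # static cut on the 1-TOM dendrogram
    merge_height: float = 0.1           # eigengene dissimilarity below which modules merge
    module_trait_r_cutoff: float = 0.6
    module_trait_p_cutoff: float = 0.005
    mm_cutoff: float = 0.8
    gs_cutoff: float = 0.7

    # supervised screen
    train_fraction: float = 0.60
    fpr_level: float = 0.10
    auc_cutoff: float = 0.85
    acc_cutoff: float = 0.85
    logfc_cutoff: float = 1.0
    logfc_direction: str = "case_over_control"  # or "control_over_case"
    rf_trees: int = 50
    rf_max_depth: int = 3
    svm_c: float = 1.0
    split_per_gene: bool = False

    # hub network
    hub_top_n: int = 10
    epc_trials: int = 1000
    dmnc_epsilon: float = 1.7
    edge_score_cutoff: float = 0.4
    mcode_node_score_cutoff: float = 0.2
    mcode_k_core: int = 2
    mcode_max_depth: int = 100
    rank_aggregation: str = "mean_rank"  # or "top_k_intersection"
    clique_budget: int = 2_000_000

    # pooling
    pool_zscale: bool = True

    # randomness
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["soft_power_grid"] = list(d["soft_power_grid"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        if "soft_power_grid" in d:
            d = dict(d)
            d["soft_power_grid"] = tuple(int(b) for b in d["soft_power_grid"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise TypeError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(d, indent=2))
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=False))


def stage_rng(seed: int, stage: str):
    """Derive a per-stage generator from the global seed.

    Uses a SeedSequence keyed by the stage name's bytes so stages are
    statistically independent and the scheme is documented/reproducible.
    """
    import numpy as np

    key = [seed] + list(stage.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence(key))


def stage_seed(seed: int, stage: str) -> int:
    """A plain integer sub-seed (< 2**31) for libraries that take int seeds."""
    return int(stage_rng(seed, stage).integers(0, 2**31 - 1))
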