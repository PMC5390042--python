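"""End-to-end orchestration: simulate/load -> classify -> binarize -> screen ->
combine -> pair screens -> phylogenetic signal -> report.

One config (YAML-serialisable) drives the whole run.  The single config
seed fans out to per-stage substreams so any stage can be rerun
independently, and every artifact is a pure function of (inputs, config):
rerunning with the same config yields bit-identical CSVs.  A manifest
records the thresholds actually applied, the seed and the artifact list.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bioactivity import CELL_LINES, build_activity_labels, labels_long_csv
from .boolean_screen import involvement_stats, pairwise_screen, top_pairs_heatmap_table
from .feature_table import (
    INTENSITY_THRESHOLD,
    binarize,
    filter_ubiquitous,
    read_peak_table,
    write_peak_table,
)
from .kappa_screen import STRONG_KAPPA, combined_score, screen
from .phylo_signal import fritz_purvis_d, read_tree, write_tree
from .synthetic_data import SyntheticConfig, simulate_study
from dendropy import Tree

logger = logging.getLogger(__name__)

ASSAYS = ("AM",) + CELL_LINES


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    out_dir: str = "phytokappa_out"
    simulate: SyntheticConfig | None = None
    peaks_csv: str | None = None
    inhibition_csv: str | None = None
    viability_csv: str | None = None
    tree_newick: str | None = None
    radius_cm: float = 0.6
    intensity_threshold: float = INTENSITY_THRESHOLD
    alpha: float = 0.05
    strong: float = STRONG_KAPPA
    operators: tuple = ("AND", "OR")
    heatmap_top_k: int = 25
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.simulate, dict):
            self.simulate = SyntheticConfig(**self.simulate)
        self.operators = tuple(self.operators)
        for name in ("radius_cm", "intensity_threshold", "alpha", "strong"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["operators"] = list(self.operators)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


@dataclass
class PipelineResult:
    out_dir: Path
    artifacts: dict = field(default_factory=dict)
    report: dict = field(default_factory=dict)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


def _stage(name):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return decorator


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _write_json(payload, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and write all artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    report: dict = {"thresholds": {
        "radius_cm": config.radius_cm,
        "intensity_threshold": config.intensity_threshold,
        "alpha": config.alpha,
        "strong": config.strong,
    }}

    @_stage("inputs")
    def load_inputs():
        if config.simulate is not None:
            study = simulate_study(config.simulate)
            write_peak_table(study.peak_table, out / "peaks.csv")
            study.inhibition.to_csv(out / "inhibition.csv", index=False)
            study.viability.to_csv(out / "viability.csv", index=False)
            write_tree(study.tree, out / "tree.nwk")
            study.truth.to_json(out / "truth.json")
            for name in ("peaks.csv", "inhibition.csv", "viability.csv", "tree.nwk", "truth.json"):
                artifacts[name] = out / name
            return study.peak_table, study.inhibition, study.viability, study.tree
        if not (config.peaks_csv and config.inhibition_csv and config.viability_csv):
            raise ValueError("either a simulate block or input paths are required")
        table = read_peak_table(config.peaks_csv)
        inhibition = pd.read_csv(config.inhibition_csv)
        viability = pd.read_csv(config.viability_csv)
        tree = read_tree(config.tree_newick) if config.tree_newick else None
        return table, inhibition, viability, tree

    table, inhibition, viability, tree = load_inputs()

    @_stage("classify")
    def classify():
        labels, details = build_activity_labels(
            inhibition, viability, radius_threshold_cm=config.radius_cm, alpha=config.alpha
        )
        long = labels_long_csv(labels, details)
        long.to_csv(out / "labels.csv", index=False)
        artifacts["labels.csv"] = out / "labels.csv"
        report["n_active"] = {
            assay: int(labels.get(assay).sum()) for assay in labels.labels.columns
        }
        return labels

    labels = classify()

    @_stage("binarize")
    def make_binary():
        bmat = binarize(table, threshold=config.intensity_threshold)
        bmat = filter_ubiquitous(bmat)
        report["n_features_after_filter"] = len(bmat.feature_ids)
        report["n_ubiquitous_removed"] = len(bmat.removed_ubiquitous)
        return bmat

    bmat = make_binary()

    @_stage("kappa_screen")
    def run_screens():
        screens = {}
        tiers = {}
        for assay in ASSAYS:
            rec = screen(bmat, labels.get(assay), assay=assay, alpha=config.alpha)
            fname = f"kappa_{assay.lower().replace('-', '')}.csv"
            rec.to_csv(out / fname, index=False)
            artifacts[fname] = out / fname
            screens[assay] = rec
            tiers[assay] = rec["strength"].value_counts().to_dict()
        report["strength_tiers"] = tiers
        return screens

    screens = run_screens()

    @_stage("combine")
    def combine():
        comb = combined_score(
            screens["AM"], screens["HaCaT"], screens["IEC-6"], strong=config.strong
        )
        table_shaped = comb.merge(
            table.features.reset_index(), on="feature_id", how="left"
        )
        table_shaped["mz"] = table_shaped["mz"].round(2)
        table_shaped["rt"] = table_shaped["rt"].round(1)
        cols = ["feature_id", "mz", "rt", "kappa_am", "kappa_hacat", "kappa_iec6",
                "kappa_combined", "rank_c", "rank_am", "rank_hacat", "rank_iec6", "selected"]
        table_shaped[cols].to_csv(out / "combined.csv", index=False)
        artifacts["combined.csv"] = out / "combined.csv"
        selected = table_shaped[table_shaped["selected"]]
        report["n_selected"] = int(selected.shape[0])
        report["selected_features"] = selected["feature_id"].tolist()
        return comb

    comb = combine()

    @_stage("pair_screens")
    def pairs():
        strong_individual = set(
            screens["AM"].loc[
                screens["AM"]["kappa"] >= config.strong, "feature_id"
            ]
        )
        pair_report = {}
        for op in config.operators:
            records, summary = pairwise_screen(
                bmat, labels.get("AM"), operator=op,
                strong=config.strong, report_threshold=config.strong,
            )
            fname = f"pairs_{op.lower()}.csv"
            records.to_csv(out / fname, index=False)
            artifacts[fname] = out / fname
            sname = f"pair_summary_{op.lower()}.json"
            summary.to_json(out / sname)
            artifacts[sname] = out / sname
            outperf = records[records["outperforming"]]
            inv = involvement_stats(outperf, strong_individual)
            pair_report[op] = {
                "n_pairs_evaluated": summary.n_pairs_evaluated,
                "n_strong": summary.n_strong,
                "n_outperforming": summary.n_outperforming,
                "best_pair_kappa": summary.best_pair_kappa,
                "best_pair": list(summary.best_pair) if summary.best_pair else None,
                "best_individual_kappa": summary.best_individual_kappa,
                "fraction_outperforming_involving_strong_individual":
                    inv.fraction_involving_focus,
                "note": summary.note,
            }
            if len(outperf) >= 1:
                indiv = screens["AM"].set_index("feature_id")["kappa"]
                k = min(config.heatmap_top_k, outperf[["feature_i", "feature_j"]].stack().nunique())
                if k >= 2:
                    mat, marginal = top_pairs_heatmap_table(outperf, k, indiv)
                    hname = f"pair_heatmap_{op.lower()}.csv"
                    mat.to_csv(out / hname)
                    artifacts[hname] = out / hname
        report["pair_screens"] = pair_report

    pairs()

    @_stage("phylo_signal")
    def dstats():
        if tree is None:
            report["dstat"] = None
            return
        results = {}
        for assay in ASSAYS:
            lab = labels.get(assay)
            if lab.nunique() < 2:
                results[assay] = {"skipped": "monomorphic classification"}
                continue
            res = fritz_purvis_d(
                tree, lab.astype(int), n_perm=config.n_perm, seed=config.seed + 1000
            )
            results[assay] = {
                "d_obs": res.d_obs, "D": res.D,
                "p_random": res.p_random, "p_brownian": res.p_brownian,
                "n_permutations": res.n_permutations,
            }
        _write_json(results, out / "dstat.json")
        artifacts["dstat.json"] = out / "dstat.json"
        report["dstat"] = results

    dstats()

    @_stage("report")
    def finalize():
        _write_json(report, out / "report.json")
        artifacts["report.json"] = out / "report.json"
        manifest = {
            "phytokappa_version": __version__,
            "seed": config.seed,
            "thresholds": report["thresholds"],
            "operators": list(config.operators),
            "n_perm": config.n_perm,
            "artifacts": sorted(artifacts),
        }
        _write_json(manifest, out / "manifest.json")
        artifacts["manifest.json"] = out / "manifest.json"

    finalize()
    return PipelineResult(out_dir=out, artifacts=artifacts, report=report)
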