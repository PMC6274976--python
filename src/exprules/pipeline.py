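"""Full-run orchestration: rank, IFS per classifier, optimal-point summary,
rule induction and the randomized-subset significance test, with a
machine-readable manifest tying the outputs together."""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import exprules
from exprules.feature_table import read_feature_table, select_features
from exprules.ifs import (
    IFSCurve,
    first_crossing,
    null_boxplot_summary,
    optimal_point,
    random_subset_null,
    run_ifs,
)
from exprules.model_eval import ALGORITHMS, ClassifierSpec
from exprules.mrmr import DiscretizationSpec, RankedFeatureList, maxrel_rank, mrmr_rank
from exprules.ripper import RipperParams, format_ruleset, ripper_train

__all__ = ["PipelineConfig", "run_pipeline", "ranking_to_frame", "curve_to_frame"]


@dataclass
class PipelineConfig:
    input_path: str
    out_dir: str
    classifiers: tuple[str, ...] = ("random_forest", "ripper")
    folds: int = 10
    seed: int = 0
    mrmr_alpha: float = 1.0
    mrmr_scheme: str = "mid"
    ripper: RipperParams = field(default_factory=RipperParams)
    signif_anchor: str | None = None
    signif_subset_size: int = 13
    signif_n_iter: int = 1000
    signif_classifier: str = "random_forest"
    crossing_thresholds: tuple[float, ...] = ()
    max_subset_size: int | None = None
    stride: int = 1
    classifier_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.classifiers:
            raise ValueError("at least one classifier is required")
        for c in self.classifiers:
            if c not in ALGORITHMS:
                raise ValueError(f"unknown classifier {c!r}")


def ranking_to_frame(ranking: RankedFeatureList) -> pd.DataFrame:
    """Ranked-list report: 1-based rank, feature name, criterion score."""
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(ranking.order) + 1),
            "feature": list(ranking.feature_names),
            "score": list(ranking.scores),
            "criterion": ranking.criterion,
        }
    )


def curve_to_frame(curve: IFSCurve) -> pd.DataFrame:
    """IFS report: one row per subset size with SN/SP/ACC/MCC."""
    rows = [
        {"n_features": i, "SN": m.SN, "SP": m.SP, "ACC": m.ACC, "MCC": m.MCC}
        for i, m in curve.points
    ]
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every enabled stage and write all reports under ``out_dir``.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": exprules.__version__,
        "seed": config.seed,
        "input": str(config.input_path),
        "stages": {},
        "outputs": {},
    }

    def stage(name: str):
        manifest["stages"][name] = {"started": time.time() - t0}
        return name

    def done(name: str) -> None:
        manifest["stages"][name]["seconds"] = round(
            time.time() - t0 - manifest["stages"][name]["started"], 3
        )

    s = stage("read")
    table = read_feature_table(config.input_path)
    done(s)

    s = stage("rank")
    dspec = DiscretizationSpec(alpha=config.mrmr_alpha)
    mrmr = mrmr_rank(table, dspec, scheme=config.mrmr_scheme)
    maxrel = maxrel_rank(table, dspec)
    for name, ranking in (("mrmr", mrmr), ("maxrel", maxrel)):
        path = out / f"ranking_{name}.tsv"
        ranking_to_frame(ranking).to_csv(path, sep="\t", index=False)
        manifest["outputs"][f"ranking_{name}"] = path.name
    done(s)

    summary_rows = []
    curves: dict[str, IFSCurve] = {}
    for algo in config.classifiers:
        s = stage(f"ifs_{algo}")
        spec = ClassifierSpec(
            algorithm=algo, params=dict(config.classifier_params.get(algo, {})), seed=config.seed
        )
        curve = run_ifs(
            table,
            mrmr,
            spec,
            k=config.folds,
            seed=config.seed,
            max_size=config.max_subset_size,
            stride=config.stride,
        )
        curves[algo] = curve
        path = out / f"ifs_{algo}.tsv"
        curve_to_frame(curve).to_csv(path, sep="\t", index=False)
        manifest["outputs"][f"ifs_{algo}"] = path.name
        size, metrics = optimal_point(curve)
        row = {
            "algorithm": algo,
            "n_features": size,
            "SN": metrics.SN,
            "SP": metrics.SP,
            "ACC": metrics.ACC,
            "MCC": metrics.MCC,
        }
        for thr in config.crossing_thresholds:
            row[f"first_crossing_{thr}"] = first_crossing(curve, thr)
        summary_rows.append(row)
        done(f"ifs_{algo}")

    path = out / "optimal_summary.tsv"
    pd.DataFrame(summary_rows).to_csv(path, sep="\t", index=False)
    manifest["outputs"]["optimal_summary"] = path.name

    if "ripper" in config.classifiers:
        s = stage("rules")
        size, _ = optimal_point(curves["ripper"])
        sub = select_features(table, mrmr.order[:size])
        params = RipperParams(
            prune_fraction=config.ripper.prune_fraction,
            min_covered=config.ripper.min_covered,
            optimization_passes=config.ripper.optimization_passes,
            dl_slack_bits=config.ripper.dl_slack_bits,
            seed=config.seed,
        )
        ruleset = ripper_train(sub, params)
        path = out / "ruleset.txt"
        path.write_text(format_ruleset(ruleset), encoding="utf-8")
        manifest["outputs"]["ruleset"] = path.name
        manifest["n_rules"] = len(ruleset.rules)
        done(s)

    if config.signif_anchor is not None:
        s = stage("significance")
        spec = ClassifierSpec(
            algorithm=config.signif_classifier,
            params=dict(config.classifier_params.get(config.signif_classifier, {})),
            seed=config.seed,
        )
        null = random_subset_null(
            table,
            anchor=config.signif_anchor,
            subset_size=config.signif_subset_size,
            spec=spec,
            n_iter=config.signif_n_iter,
            k=config.folds,
            seed=config.seed,
        )
        path = out / "null_mccs.tsv"
        pd.DataFrame({"iteration": np.arange(1, len(null.mccs) + 1), "MCC": null.mccs}).to_csv(
            path, sep="\t", index=False
        )
        manifest["outputs"]["null_mccs"] = path.name
        summary = null_boxplot_summary(null)
        path = out / "null_summary.json"
        path.write_text(json.dumps(summary, indent=2), encoding="utf-8")
        manifest["outputs"]["null_summary"] = path.name
        done(s)

    manifest["wall_seconds"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest
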