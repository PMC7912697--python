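"""End-to-end orchestration: input -> estimate -> compare -> decode.

A single YAML configuration drives all stages; a master seed spawns
independent per-stage random streams so changing, say, the number of CV
repetitions does not perturb the estimation results.  Every run writes a
manifest (config echo, per-stage seeds, package versions, row counts) that
fully determines the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decoding import build_features, compare_feature_sets, knn_classify, rusboost_classify
from .embedding import InsufficientSamplesError, estimate_ais, optimize_past_state
from .group import results_to_table, run_group_analysis
from .io import read_aoi_layout, read_gaze_log, read_scanpaths, write_scanpaths
from .preprocessing import Scanpath, TrialUnusableError, preprocess_recording
from .synthetic import StudyDesign, generate_study

__all__ = ["RunConfig", "run_pipeline", "estimate_study"]

logger = logging.getLogger(__name__)

_STAGES = ("input", "estimate", "compare", "decode")


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 1
    input_kind: str = "simulate"  # or "gaze" / "scanpaths"
    gaze_file: str | None = None
    aoi_file: str | None = None
    scanpath_file: str | None = None
    study: dict = dataclasses.field(default_factory=dict)
    min_confidence: float = 0.9
    max_dispersion: float = 50.0
    min_duration: float = 100.0
    max_duration: float = 1500.0
    k_max: int = 5
    selection_n_perm: int = 200
    alpha: float = 0.05
    bias_correction: str = "pt"
    final_n_perm: int = 5000
    compare_n_perm: int = 5000
    decode_features: tuple[str, ...] = ("ais", "gte")
    decode_classifiers: tuple[str, ...] = ("knn",)
    folds: int = 5
    repetitions: int = 10
    knn_k: int = 1
    rusboost_rounds: int = 50

    def __post_init__(self) -> None:
        if self.input_kind not in {"simulate", "gaze", "scanpaths"}:
            raise ValueError(f"unknown input kind: {self.input_kind!r}")
        if self.input_kind == "gaze" and not (self.gaze_file and self.aoi_file):
            raise ValueError("gaze input requires gaze_file and aoi_file")
        if self.input_kind == "scanpaths" and not self.scanpath_file:
            raise ValueError("scanpath input requires scanpath_file")
        for path in (self.gaze_file, self.aoi_file, self.scanpath_file):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.bias_correction not in {"pt", "mm", "none"}:
            raise ValueError("bias_correction must be pt, mm or none")
        for name in ("k_max", "selection_n_perm", "compare_n_perm", "folds", "repetitions"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        for key in ("decode_features", "decode_classifiers"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["decode_features"] = list(self.decode_features)
        d["decode_classifiers"] = list(self.decode_classifiers)
        return d


def _stage_seeds(master: int) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(len(_STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(_STAGES, children)
    }


def estimate_study(
    scanpaths: list[Scanpath],
    k_max: int = 5,
    selection_n_perm: int = 200,
    alpha: float = 0.05,
    bias_correction: str = "pt",
    final_n_perm: int = 5000,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Optimize a past state and estimate AIS for every trial.

    Returns the tidy per-trial table and the spec per (participant, trial);
    trials too short to embed are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    results = []
    specs = {}
    for sp in scanpaths:
        try:
            spec = optimize_past_state(
                sp, k_max=k_max, n_perm=selection_n_perm, alpha=alpha, seed=rng
            )
            res = estimate_ais(
                sp,
                spec,
                correct_bias=bias_correction != "none",
                bias_method=bias_correction if bias_correction != "none" else "pt",
                n_perm=final_n_perm,
                seed=rng,
            )
        except InsufficientSamplesError as exc:
            logger.warning("skipping %s/%s: %s", sp.participant_id, sp.trial_id, exc)
            continue
        specs[(sp.participant_id, sp.trial_id)] = spec
        results.append(res)
    return results_to_table(results), specs


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute all stages and write per-stage tables plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict[str, Any] = {
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "versions": {"scanpath_ais": __version__, "numpy": np.__version__},
        "row_counts": {},
    }

    # -- input ---------------------------------------------------------------
    if config.input_kind == "simulate":
        design = StudyDesign(**config.study)
        study = generate_study(design, seed=seeds["input"])
        scanpaths = list(study.scanpaths)
    elif config.input_kind == "gaze":
        layout = read_aoi_layout(config.aoi_file)
        scanpaths = []
        for rec in read_gaze_log(config.gaze_file):
            try:
                _, sp = preprocess_recording(
                    rec,
                    layout,
                    min_confidence=config.min_confidence,
                    max_dispersion=config.max_dispersion,
                    min_duration=config.min_duration,
                    max_duration=config.max_duration,
                )
            except TrialUnusableError as exc:
                logger.warning("%s", exc)
                continue
            if sp is not None:
                scanpaths.append(sp)
    else:
        scanpaths = read_scanpaths(config.scanpath_file)
    write_scanpaths(scanpaths, out / "scanpaths.csv")
    manifest["row_counts"]["scanpaths"] = len(scanpaths)

    # -- estimate ------------------------------------------------------------
    trial_table, specs = estimate_study(
        scanpaths,
        k_max=config.k_max,
        selection_n_perm=config.selection_n_perm,
        alpha=config.alpha,
        bias_correction=config.bias_correction,
        final_n_perm=config.final_n_perm,
        seed=seeds["estimate"],
    )
    trial_table.to_csv(out / "trial_results.csv", index=False)
    manifest["row_counts"]["trial_results"] = len(trial_table)

    # -- compare -------------------------------------------------------------
    report = run_group_analysis(
        scanpaths,
        k_max=config.k_max,
        selection_n_perm=config.selection_n_perm,
        selection_alpha=config.alpha,
        n_perm=config.compare_n_perm,
        seed=seeds["compare"],
        specs=specs,
    )
    report.tests.to_csv(out / "group_tests.csv", index=False)
    report.trial_table.to_csv(out / "equalized_trials.csv", index=False)
    manifest["row_counts"]["group_tests"] = len(report.tests)

    # -- decode --------------------------------------------------------------
    decode_rows = []
    reports = {}
    for feature in config.decode_features:
        try:
            features = build_features(trial_table, feature=feature)
        except ValueError as exc:
            logger.warning("decoding feature %s skipped: %s", feature, exc)
            continue
        for clf in config.decode_classifiers:
            if clf == "knn":
                rep = knn_classify(
                    features,
                    k=config.knn_k,
                    folds=config.folds,
                    repetitions=config.repetitions,
                    seed=seeds["decode"],
                )
            elif clf == "rusboost":
                rep = rusboost_classify(
                    features,
                    n_rounds=config.rusboost_rounds,
                    folds=config.folds,
                    repetitions=config.repetitions,
                    seed=seeds["decode"],
                )
            else:
                raise ValueError(f"unknown classifier: {clf!r}")
            reports[(feature, clf)] = rep
            decode_rows.append(
                {
                    "feature": feature,
                    "classifier": clf,
                    "mean_accuracy": rep.mean_accuracy,
                    "sd_accuracy": rep.sd_accuracy,
                    "majority_baseline": rep.majority_baseline,
                }
            )
    pd.DataFrame(decode_rows).to_csv(out / "decoding.csv", index=False)
    manifest["row_counts"]["decoding"] = len(decode_rows)
    if ("ais", "knn") in reports and ("gte", "knn") in reports:
        cmp = compare_feature_sets(reports[("ais", "knn")], reports[("gte", "knn")])
        manifest["ais_vs_gte_knn"] = {
            "statistic": cmp.statistic,
            "p_value": cmp.p_value,
            "n_pairs": cmp.n_pairs,
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
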