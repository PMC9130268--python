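"""End-to-end experiment runner with a reproducibility manifest.

``run_experiment`` chains the stages in the study order — simulate (or
load) -> preprocess -> feature generation -> PCA + leave-one-animal-out
training/evaluation -> report — optionally for both feature arms (with and
without spatial features), and writes per-fold counts, report matrices, the
ANOVA comparison and a JSON manifest (config hash, timings, output
checksums, warnings) to the output directory.  A single master seed drives
every stochastic stage through derived substreams, so identical configs
yield identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortParams, generate_cohort, read_cohort
from .evaluation import anova_compare, build_report, fold_frame
from .features import FeatureConfig, build_feature_table
from .model import ClassifierSpec, default_classifier_specs, loo_crossvalidate
from .preprocessing import PreprocessConfig, preprocess
from .types import ParameterError

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_experiment", "preprocess_cohort"]


@dataclass
class RunConfig:
    """Serializable configuration of one experiment run."""

    cohort: CohortParams = field(default_factory=CohortParams)
    input_dir: str | None = None  # load a written cohort instead of simulating
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    classifiers: tuple[str, ...] = ("RF", "RB", "AB", "SVM_lin", "SVM_gauss")
    spatial_arms: tuple[bool, ...] = (True, False)
    seed: int = 0
    variance_target: float = 0.99
    subsample_fraction: float = 0.01
    pca_scope: str = "fold"
    output_dir: str = "results/run"

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        payload = self.to_dict()
        payload.pop("output_dir", None)  # where results land is not semantic
        blob = yaml.safe_dump(_plain(payload), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stage_seconds: dict[str, float]
    output_checksums: dict[str, str]
    warnings: list[str]
    failed_stage: str | None = None


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def preprocess_cohort(samples, config: PreprocessConfig):
    """Preprocess every animal; yields build_feature_table input tuples."""
    processed = []
    for s in samples:
        res = preprocess(s.image, s.lesion_mask, config)
        processed.append((s.animal_id, s.model_group, res.image, res.valid,
                          s.lesion_mask))
    return processed


def _fold_counts_frame(results_by_arm) -> pd.DataFrame:
    rows = []
    for arm, by_clf in results_by_arm.items():
        for clf, folds in by_clf.items():
            for f in folds:
                from .evaluation import fold_metrics

                ms = fold_metrics(f)
                rows.append({"arm": arm, "classifier": clf, "fold": f.animal_id,
                             "model_group": f.model_group,
                             "TP": f.tp, "TN": f.tn, "FP": f.fp, "FN": f.fn,
                             "AUC": ms.auc, "MCC": ms.mcc,
                             "ACC": ms.acc, "ACC2": ms.acc2})
    return pd.DataFrame(rows)


def run_experiment(config: RunConfig) -> RunManifest:
    """Execute the full pipeline; returns the written manifest.

    On stage failure, outputs of completed stages are preserved and the
    manifest records the failure point.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    warnings_log: list[str] = []
    checksums: dict[str, str] = {}
    failed = None

    handler = _ListHandler(warnings_log)
    logging.getLogger("mscolo").addHandler(handler)
    try:
        stage = "simulate"
        t0 = time.perf_counter()
        if config.input_dir:
            samples = read_cohort(config.input_dir)
        else:
            samples = generate_cohort(config.cohort)
        timings[stage] = time.perf_counter() - t0

        stage = "preprocess"
        t0 = time.perf_counter()
        processed = preprocess_cohort(samples, config.preprocessing)
        timings[stage] = time.perf_counter() - t0

        stage = "features+crossvalidate"
        t0 = time.perf_counter()
        specs = [ClassifierSpec(k) for k in config.classifiers]
        results_by_arm = {}
        for spatial in config.spatial_arms:
            fc = dataclasses.replace(config.features, spatial=spatial)
            table = build_feature_table(processed, fc)
            arm = "with_spatial" if spatial else "without_spatial"
            results_by_arm[arm] = loo_crossvalidate(
                table, specs, seed=config.seed,
                variance_target=config.variance_target,
                subsample_fraction=config.subsample_fraction,
                pca_scope=config.pca_scope)
        timings[stage] = time.perf_counter() - t0

        stage = "report"
        t0 = time.perf_counter()
        folds_path = out / "folds.csv"
        _fold_counts_frame(results_by_arm).to_csv(folds_path, index=False)
        for name, matrix in build_report(results_by_arm).items():
            matrix.to_csv(out / f"report_{name}.csv")
        frame = fold_frame(results_by_arm)
        frame.to_csv(out / "fold_metrics_long.csv", index=False)
        try:
            anova = anova_compare(frame)
            (out / "anova.json").write_text(json.dumps(anova.factors, indent=2))
        except ParameterError as exc:
            warnings_log.append(f"anova skipped: {exc}")
        timings[stage] = time.perf_counter() - t0
    except Exception:
        failed = stage
        raise
    finally:
        logging.getLogger("mscolo").removeHandler(handler)
        for path in sorted(out.glob("*.csv")) + sorted(out.glob("*.json")):
            if path.name != "manifest.json":
                checksums[path.name] = _checksum(path)
        manifest = RunManifest(config_hash=config.hash(), version=__version__,
                               stage_seconds=timings, output_checksums=checksums,
                               warnings=warnings_log, failed_stage=failed)
        tmp = out / "manifest.json.tmp"
        tmp.write_text(json.dumps(asdict(manifest), indent=2))
        tmp.replace(out / "manifest.json")  # atomic write at run end
    return manifest


class _ListHandler(logging.Handler):
    def __init__(self, sink: list[str]):
        super().__init__(level=logging.WARNING)
        self._sink = sink

    def emit(self, record):
        self._sink.append(record.getMessage())
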