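"""Leave-one-animal-out evaluation of the five classifiers on each cohort.

Per fold: PCA (99% variance) is refit on the training animals, training
rows are subsampled, the classifier is fitted and the held-out animal is
predicted in full.  Per-fold confusion counts and metrics go to
results/folds_<cohort>.csv for both feature arms.
"""

import sys
from pathlib import Path

from mscolo import read_cohort
from mscolo.features import FeatureConfig, build_feature_table
from mscolo.model import default_classifier_specs, loo_crossvalidate
from mscolo.pipeline import _fold_counts_frame
from mscolo.evaluation import fold_frame

sys.path.insert(0, str(Path(__file__).resolve().parent))
from importlib import import_module

load_processed = import_module("03_extract_features").load_processed

ROOT = Path(__file__).resolve().parents[1]
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
SUBSAMPLE_FRACTION = 0.05  # ~1.5k training rows at desk scale


def main():
    for cohort_dir in sorted((ROOT / "scratch" / "cohorts").iterdir()):
        prep_dir = ROOT / "scratch" / "preprocessed" / cohort_dir.name
        if not prep_dir.exists():
            continue
        processed = load_processed(cohort_dir, prep_dir)
        results = {}
        for arm, spatial in (("with_spatial", True), ("without_spatial", False)):
            table = build_feature_table(processed, FeatureConfig(spatial=spatial))
            results[arm] = loo_crossvalidate(
                table, default_classifier_specs(), seed=SEED,
                subsample_fraction=SUBSAMPLE_FRACTION)
        _fold_counts_frame(results).to_csv(
            ROOT / "results" / f"folds_{cohort_dir.name}.csv", index=False)
        fold_frame(results).to_csv(
            ROOT / "results" / f"fold_metrics_long_{cohort_dir.name}.csv",
            index=False)
        print(f"{cohort_dir.name}: wrote per-fold results for both arms")


if __name__ == "__main__":
    main()
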