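"""Build the per-pixel feature tables for both feature arms.

For every preprocessed cohort, assembles the full table (intensity, Sobel,
spectral-spatial variation, Gauss-Laguerre bank; 169 columns) and the
intensity-only table (7 columns), saves them under scratch/features/, and
records table sizes plus the PCA component count at the 99% variance target
in results/feature_summary.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mscolo import read_cohort
from mscolo.features import FeatureConfig, build_feature_table
from mscolo.model import fit_pca
from mscolo.types import PixelMask

ROOT = Path(__file__).resolve().parents[1]


def load_processed(cohort_dir: Path, prep_dir: Path):
    processed = []
    for s in read_cohort(cohort_dir):
        image = s.image.__class__(
            np.load(prep_dir / f"{s.animal_id}_processed.npy"), s.image.bands)
        valid = PixelMask(np.load(prep_dir / f"{s.animal_id}_valid.npy"),
                          provenance="combined")
        processed.append((s.animal_id, s.model_group, image, valid,
                          s.lesion_mask))
    return processed


def main():
    rows = []
    feat_dir = ROOT / "scratch" / "features"
    feat_dir.mkdir(parents=True, exist_ok=True)
    for cohort_dir in sorted((ROOT / "scratch" / "cohorts").iterdir()):
        prep_dir = ROOT / "scratch" / "preprocessed" / cohort_dir.name
        if not prep_dir.exists():
            continue
        processed = load_processed(cohort_dir, prep_dir)
        for arm, spatial in (("with_spatial", True), ("without_spatial", False)):
            table = build_feature_table(processed, FeatureConfig(spatial=spatial))
            np.savez_compressed(
                feat_dir / f"{cohort_dir.name}_{arm}.npz",
                X=table.X, y=table.y,
                animal_id=table.index["animal_id"].to_numpy(dtype="U64"),
                model_group=table.index["model_group"].to_numpy(dtype="U32"))
            pca = fit_pca(table, 0.99)
            rows.append({"cohort": cohort_dir.name, "arm": arm,
                         "rows": table.n_rows, "features": table.n_features,
                         "pca_components_99pct": pca.n_components})
            print(f"{cohort_dir.name} {arm}: {table.n_rows} px x "
                  f"{table.n_features} features -> {pca.n_components} PCs")
    pd.DataFrame(rows).to_csv(ROOT / "results" / "feature_summary.csv",
                              index=False)


if __name__ == "__main__":
    main()
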