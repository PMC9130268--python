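"""Aggregate the cross-validation folds into report tables and the ANOVA.

For every cohort: the classifier x metric matrices per feature arm and
tumour-model subgroup, the MCC-by-arm-and-subgroup table, and a threefold
fixed-effects ANOVA (classifier x metric x spatial features) with partial
eta squared per factor.  Everything lands under results/.
"""

import json
from pathlib import Path

import pandas as pd

from mscolo.evaluation import anova_compare, report_from_frame

ROOT = Path(__file__).resolve().parents[1]


def main():
    for path in sorted((ROOT / "results").glob("fold_metrics_long_*.csv")):
        cohort = path.stem.replace("fold_metrics_long_", "")
        frame = pd.read_csv(path)
        for name, matrix in report_from_frame(frame).items():
            matrix.round(3).to_csv(ROOT / "results" / f"report_{cohort}_{name}.csv")
        anova = anova_compare(frame)
        (ROOT / "results" / f"anova_{cohort}.json").write_text(
            json.dumps(anova.factors, indent=2))
        print(f"== {cohort} ==")
        print(report_from_frame(frame, groups=False)["all_with_spatial"].round(3))
        etas = {k: round(v["partial_eta_sq"], 3)
                for k, v in anova.factors.items()}
        print(f"ANOVA partial eta^2: {etas}\n")


if __name__ == "__main__":
    main()
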