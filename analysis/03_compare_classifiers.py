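"""Compare learners on the f1-optimal feature set.

Feeds the identical train/validation partitions and selected channels
to a Random Forest, two SVM solver variants and a single Gini decision
tree, reporting mean and relative standard deviation of each validation
metric over the experiments.
"""

import argparse
import json
from pathlib import Path

from mzmarker.io import load_feature_table, normalize_rows
from mzmarker.learning import compare_classifiers, make_experiments, split_fit_test


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--in-dir", type=Path, default=Path("results"))
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    matrix = normalize_rows(load_feature_table(args.in_dir / "cohort.csv"))
    selected = json.loads((args.in_dir / "optimal_channels.json").read_text())
    plan = make_experiments(
        split_fit_test(matrix.patient_class, 0.2, args.seed), 10, 0.2, args.seed
    )
    fit = matrix.subset_patients(plan.all_fit())
    table = compare_classifiers(fit, plan, selected, seed=args.seed)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out_dir / "classifier_comparison.csv", index=False)
    with_pct = table.copy()
    for col in with_pct.columns:
        if col.startswith("mean_"):
            with_pct[col] = (100 * with_pct[col]).round(1)
    print(with_pct.to_string(index=False))


if __name__ == "__main__":
    main()
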