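"""Classical statistics of the virtual database.

Ordinary-least-squares coefficient t-tests for each target on its feature
set, and the pairwise Pearson correlation matrix of the full table.

Usage: python analysis/04_linear_statistics.py --dataset results/dataset.csv
"""

import argparse
from pathlib import Path

import pandas as pd

from hemopred.dataset import FEATURE_COLUMNS, TARGET_COLUMNS, read_dataset
from hemopred.evaluation import correlation_matrix, ols_coefficient_tests

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--dataset", type=Path, default=Path("results/dataset.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table = read_dataset(args.dataset, require_targets=True).table
    frames = []
    for target, col in TARGET_COLUMNS.items():
        feats = ["brSBP", "brDBP", "cfPWV", "HR"] + (
            ["EF"] if target == "E_es" else []
        )
        X = table[[FEATURE_COLUMNS[f] for f in feats]]
        X.columns = feats
        out = ols_coefficient_tests(X, table[col])
        out.insert(0, "target", target)
        frames.append(out)
        print(f"\nOLS t-statistics for {target}:")
        print(out.round(4).to_string(index=False))
    pd.concat(frames, ignore_index=True).to_csv(
        args.out / "ols_coefficients.csv", index=False
    )
    corr = correlation_matrix(table.drop(columns="subject_id"))
    corr.to_csv(args.out / "correlation_matrix.csv")
    print("\ncorrelation matrix written to results/correlation_matrix.csv")
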