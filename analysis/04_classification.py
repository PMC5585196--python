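#!/usr/bin/env python
"""Leave-one-out SVM classification: diagnosis and one-against-all severity.

Runs LOOCV in both feature-selection scopes (pooled = filter once on the
full cohort; per_fold = leakage-safe filtering inside every fold) for the
binary diagnosis task and the three severity tasks, reporting the exact
binomial significance of every accuracy and, for severity, the accuracy
restricted to the patient test rounds.
"""

import argparse
from pathlib import Path

import pandas as pd

from inph_rsfc.classify import ClassifierConfig, TASKS, accuracy_percent, loocv
from inph_rsfc.pipeline import build_labeled_features
from inph_rsfc.simulate import SimConfig, read_cohort, simulate_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort_dir = args.out / "cohort"
    cohort = (
        read_cohort(cohort_dir)
        if cohort_dir.exists()
        else simulate_cohort(config=SimConfig(seed=args.seed))
    )
    ds = build_labeled_features(cohort)

    rows = []
    for scope in ("pooled", "per_fold"):
        cfg = ClassifierConfig(selection_scope=scope)
        for task in TASKS:
            res = loocv(ds, task, cfg)
            rows.append(
                {
                    "task": task,
                    "scope": scope,
                    "correct": res.n_correct,
                    "n": res.n_folds,
                    "accuracy_pct": accuracy_percent(res.n_correct, res.n_folds),
                    "p_binomial": res.p_binomial,
                    "chance": res.chance_level,
                    "restricted_correct": res.restricted_correct,
                    "restricted_n": res.restricted_n,
                }
            )
            line = (
                f"{task:13s} [{scope:8s}] {res.n_correct:2d}/{res.n_folds} "
                f"({accuracy_percent(res.n_correct, res.n_folds)}%), "
                f"p = {res.p_binomial:.3g} at chance {res.chance_level:.2f}"
            )
            if res.restricted_n:
                line += (
                    f"; patients only {res.restricted_correct}/{res.restricted_n}"
                )
            print(line)

    args.out.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame(rows)
    table.to_csv(args.out / "classification.tsv", sep="\t", index=False)
    print(f"wrote {args.out / 'classification.tsv'}")


if __name__ == "__main__":
    main()
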