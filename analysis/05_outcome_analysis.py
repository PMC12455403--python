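"""Relate resection-overlap categories to postoperative seizure freedom.

Joins the overlap table with the outcome table and computes: year-1
seizure-freedom rates with 90% Wilson intervals per group, Kaplan-Meier
curves and the log-rank test (largest cluster resected vs spared), and
rank-based comparisons of substantial-cluster count and total volume
between seizure-free and not seizure-free subjects.  Writes
results/05_outcome_stats.json and results/05_km_curves.csv.
"""

import json
from pathlib import Path

import pandas as pd

from dwiclust.cli import _load_cohort_dir
from dwiclust.outcomes import (
    compare_counts,
    km_logrank,
    proportion_ci90,
    seizure_free_at,
    to_survival,
)

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    _, _, _, _, outcomes = _load_cohort_dir(COHORT_DIR)
    overlap = pd.read_csv(RESULTS / "04_overlap_table.csv")
    outcome_by_id = {o.subject_id: o for o in outcomes}
    overlap["seizure_free_y1"] = [
        seizure_free_at(outcome_by_id[s], 1) for s in overlap.subject_id
    ]
    overlap["resected"] = overlap.fraction_largest > 0

    stats: dict = {}
    for name, sub in overlap.groupby("resected"):
        label = "largest_resected" if name else "largest_spared"
        est, lo, hi = proportion_ci90(int(sub.seizure_free_y1.sum()), len(sub))
        stats[f"year1_rate_{label}"] = {
            "rate": est, "ci90": [lo, hi], "n": len(sub),
        }
        print(f"{label}: {100 * est:.0f}% seizure-free at year 1 "
              f"(90% CI {100 * lo:.0f}-{100 * hi:.0f}, n={len(sub)})")

    groups = {
        label: [to_survival(outcome_by_id[s]) for s in sub.subject_id]
        for label, sub in (
            ("largest_resected", overlap[overlap.resected]),
            ("largest_spared", overlap[~overlap.resected]),
        )
        if len(sub)
    }
    if len(groups) == 2:
        curves, logrank = km_logrank(groups)
        curves.to_csv(RESULTS / "05_km_curves.csv", index=False)
        stats["logrank"] = {"chi2": logrank.statistic, "p": logrank.p_value}
        print(f"log-rank resected vs spared: chi2={logrank.statistic:.2f}, "
              f"p={logrank.p_value:.2g}")

    sf = overlap[overlap.seizure_free_y1 == True]
    nsf = overlap[overlap.seizure_free_y1 == False]
    if len(sf) and len(nsf):
        count_test = compare_counts(sf.n_substantial, nsf.n_substantial)
        stats["cluster_count_vs_outcome"] = {
            "W": count_test.statistic, "p": count_test.p_value,
        }
        print(f"substantial-cluster count, seizure-free vs not: "
              f"p={count_test.p_value:.2f}")

    (RESULTS / "05_outcome_stats.json").write_text(json.dumps(stats, indent=2))


if __name__ == "__main__":
    main()
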