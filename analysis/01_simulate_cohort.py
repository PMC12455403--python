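"""Generate the synthetic study cohort and write it to disk.

Produces a seeded cohort of 30 controls and 40 patients on a 32^3 grid at
2 mm: smooth MD-like control volumes, patients with planted abnormality
clusters (one dominant), spherical resection masks hitting per-patient
overlap targets, and yearly ILAE outcomes whose year-1 seizure-freedom
probability is 0.83 when the largest planted cluster is resected and 0.55
when it is spared.

Volumes go to scratch/cohort/ (NIfTI); the ground-truth summary table goes
to results/01_cohort_truth.csv.
"""

from pathlib import Path

import pandas as pd

from dwiclust.synthetic import SyntheticConfig, generate_cohort, write_cohort

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

CONFIG = SyntheticConfig(seed=0, n_controls=30, n_patients=40)


def main() -> None:
    cohort = generate_cohort(CONFIG)
    write_cohort(cohort, COHORT_DIR)

    rows = []
    for sid, gt in cohort.ground_truth.items():
        rows.append(
            {
                "subject_id": sid,
                "planted_sizes_voxels": "|".join(map(str, gt.cluster_sizes)),
                "overlap_target": gt.overlap_target,
                "achieved_overlap": gt.achieved_overlap,
                "largest_resected": gt.largest_resected,
            }
        )
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "01_cohort_truth.csv", index=False)

    n_res = int(df["largest_resected"].sum())
    print(f"wrote cohort to {COHORT_DIR}")
    print(
        f"{CONFIG.n_controls} controls, {CONFIG.n_patients} patients "
        f"({n_res} with the planted largest cluster resected, "
        f"{CONFIG.n_patients - n_res} spared)"
    )


if __name__ == "__main__":
    main()
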