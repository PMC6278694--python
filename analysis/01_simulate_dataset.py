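#!/usr/bin/env python
"""Simulate a spring-flowering-time-like historical dataset with gross-outlier
contamination and write it in the study/assay file layout.

The generated collection mimics seed-regeneration data: 300 accessions over
25 years with cohort-block missingness (entry cohorts regenerated every ~3
years), ~1% duplicate plots, and 1% of records shifted by +-8 error SD.
Outputs go to results/synthetic/.
"""

import argparse
from pathlib import Path

from histpheno import data_io
from histpheno.synthetic_data import SimulationParams, simulate_dataset

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=20180278)
    args = ap.parse_args()

    params = SimulationParams(
        n_genotypes=300, n_years=25, missingness="cohort_blocks",
        regen_interval=3, dup_rate=0.01, outlier_rate=0.01,
        outlier_shift_sd=8.0, seed=args.seed)
    dataset, truth = simulate_dataset(params)

    OUT.mkdir(parents=True, exist_ok=True)
    data_io.write_assay(dataset, OUT / "a_Historical.Data_Spring.txt")
    data_io.write_study(list(dataset.study.values()), OUT / "s_Spring_Barley.txt")
    truth.records.to_csv(OUT / "truth_records.txt", sep="\t", index=False)

    per_year = dataset.records.groupby("harvest_year").size()
    print(f"wrote {dataset.n_records} records for {len(dataset.accessions)} "
          f"accessions across {len(dataset.years)} years -> {OUT}")
    print(f"records per year: min {per_year.min()}, max {per_year.max()}")
    print(f"true contaminated records: {int(truth.records['outlier'].sum())}")
    print(f"duplicate plots: "
          f"{int((dataset.records['replicate_index'] > 1).sum())}")


if __name__ == "__main__":
    main()
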