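#!/usr/bin/env python
"""Quantitative-genetic summaries of the historical vs enhanced dataset:
heritability, per-year coefficients of variation, year-pair correlations and
the origin frequency table.
"""

from pathlib import Path

from histpheno import data_io
from histpheno.genetics_summaries import (heritability_from_fit, origin_table,
                                          year_cv, year_pair_correlations)
from histpheno.mm_engine import ModelSpec, fit

BASE = Path(__file__).resolve().parents[1] / "results"
OUT = BASE / "summaries"


def main() -> None:
    historical = data_io.read_assay(
        BASE / "synthetic" / "a_Historical.Data_Spring.txt", "FT", "spring")
    enhanced = data_io.read_assay(
        BASE / "curation" / "Data.corrected.FT.txt", "FT", "spring")
    OUT.mkdir(parents=True, exist_ok=True)

    lines = ["dataset\tsigma2_G\tsigma2_Y\tsigma2_e_bar\tE_bar\th2"]
    for name, ds in (("historical", historical), ("enhanced", enhanced)):
        f = fit(ds, ModelSpec.variance_components())
        h2 = heritability_from_fit(f)
        lines.append(f"{name}\t{f.varcomp.sigma2_G:.2f}\t{f.varcomp.sigma2_Y:.2f}"
                     f"\t{h2.sigma2_e_bar:.2f}\t{h2.E_bar:.2f}\t{h2.h2_rounded:.2f}")
        print(f"{name}: s2_G={f.varcomp.sigma2_G:.2f} "
              f"s2_e_bar={h2.sigma2_e_bar:.2f} E_bar={h2.E_bar:.2f} "
              f"h2={h2.h2_rounded:.2f}")
    (OUT / "heritability.txt").write_text("\n".join(lines) + "\n")

    cv = year_cv(fit(enhanced, ModelSpec.year_fixed()))
    cv.table.to_csv(OUT / "year_cv.txt", sep="\t", index=False,
                    float_format="%.6g")
    print(f"year CV (enhanced): mean {cv.mean_cv:.3f} +- {cv.sd_cv:.3f}, "
          f"range {cv.min_cv:.3f}-{cv.max_cv:.3f}")

    corr = year_pair_correlations(enhanced, min_overlap=50)
    corr.table.to_csv(OUT / "year_pair_correlations.txt", sep="\t",
                      index=False, float_format="%.6g")
    print(f"year-pair correlations (>=50 shared accessions): "
          f"mean r {corr.mean_r:.2f} over {corr.n_pairs} pairs")

    study = data_io.read_study(BASE / "synthetic" / "s_Spring_Barley.txt")
    tab = origin_table(study)
    tab.to_csv(OUT / "origin_table.txt", sep="\t", index=False)
    print(f"top origin: {tab.iloc[0]['origin']} "
          f"({tab.iloc[0]['percent']}% of accessions)")


if __name__ == "__main__":
    main()
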