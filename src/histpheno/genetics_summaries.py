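"""Quantitative-genetic summary statistics of a curated dataset.

* entry-mean heritability h2 = s2_G / (s2_G + s2_e_bar / Y_bar), with s2_G the
  genetic variance, s2_e_bar the average of the per-year error variances and
  Y_bar the average number of distinct years in which a genotype was tested;
* per-year coefficient of variation cv_y = sqrt(s2_e,y) / year mean, from the
  year-fixed model;
* Pearson correlations between year pairs sharing at least ``min_overlap``
  accessions (within-year replicates averaged first);
* origin (country of collection) frequency tables with an "Others" tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import HistoricalDataset, StudyRow
from .errors import UsageError
from .mm_engine import FitResult


@dataclass(frozen=True)
class HeritabilityResult:
    """h2 together with the three quantities it is computed from."""

    h2: float
    sigma2_G: float
    sigma2_e_bar: float
    E_bar: float

    @property
    def h2_rounded(self) -> float:
        """h2 at the 2-decimal reporting precision."""
        return round(self.h2, 2)


def heritability(sigma2_G: float, sigma2_e_bar: float, E_bar: float) -> HeritabilityResult:
    """Entry-mean heritability on unbalanced data.

    h2 = sigma2_G / (sigma2_G + sigma2_e_bar / E_bar).  ``E_bar`` is the
    average number of years a genotype was tested; it divides the error
    variance because the accession mean averages over that many environments.
    """
    if E_bar < 1:
        raise UsageError("E_bar must be >= 1 (every genotype has >= 1 year)")
    if sigma2_G < 0 or sigma2_e_bar < 0:
        raise UsageError("variances must be non-negative")
    if sigma2_G == 0 and sigma2_e_bar == 0:
        raise UsageError("h2 undefined when all variance is zero")
    h2 = sigma2_G / (sigma2_G + sigma2_e_bar / E_bar)
    return HeritabilityResult(h2=float(h2), sigma2_G=float(sigma2_G),
                              sigma2_e_bar=float(sigma2_e_bar), E_bar=float(E_bar))


def heritability_from_fit(fit: FitResult) -> HeritabilityResult:
    """h2 from a variance-component fit (genotypes and years random)."""
    if fit.spec.genotype_role != "random":
        raise UsageError("heritability needs a fit with random genotype effects")
    return heritability(fit.varcomp.sigma2_G, fit.varcomp.sigma2_e_bar, fit.E_bar)


@dataclass
class YearCV:
    """Per-year coefficients of variation and their summaries.

    ``table`` columns: year, sigma2_e, year_mean, cv.  Years whose estimated
    mean is non-positive get cv = NaN (with a warning); summaries are over the
    defined values only.
    """

    table: pd.DataFrame
    mean_cv: float
    sd_cv: float
    min_cv: float
    max_cv: float


def year_cv(fit: FitResult) -> YearCV:
    """Per-year CV from a year-fixed fit: sqrt(s2_e,y) / (mu + year effect)."""
    if fit.spec.year_role != "fixed" or fit.spec.genotype_role != "random":
        raise UsageError("year_cv needs the year-fixed model "
                         "(genotypes random, years fixed)")
    rows = []
    for year in sorted(fit.year_effects):
        s2e = fit.varcomp.sigma2_e_by_year[year]
        year_mean = fit.mu_hat + fit.year_effects[year]
        if year_mean <= 0:
            warnings.warn(f"year {year}: estimated mean {year_mean:.3g} <= 0; "
                          "CV undefined", stacklevel=2)
            cv = np.nan
        else:
            cv = float(np.sqrt(s2e) / year_mean)
        rows.append((year, s2e, year_mean, cv))
    table = pd.DataFrame(rows, columns=["year", "sigma2_e", "year_mean", "cv"])
    cvs = table["cv"].dropna()
    return YearCV(
        table=table,
        mean_cv=float(cvs.mean()),
        sd_cv=float(cvs.std(ddof=1)) if len(cvs) > 1 else 0.0,
        min_cv=float(cvs.min()),
        max_cv=float(cvs.max()),
    )


@dataclass
class YearPairCorrelations:
    """Pearson correlations between pairs of years with sufficient overlap."""

    table: pd.DataFrame  # year_a, year_b, n_common, r
    mean_r: float  # NaN when no pair qualifies
    n_pairs: int


def year_pair_correlations(dataset: HistoricalDataset,
                           min_overlap: int = 50) -> YearPairCorrelations:
    """Correlate accession values between every pair of years that share at
    least ``min_overlap`` accessions.

    Within-year replicate plots are averaged first, so the correlation is
    between accession-level values.  Pairs below the overlap threshold are
    excluded from both the table and the count.
    """
    wide = dataset.cell_means()
    years = sorted(wide.columns)
    rows = []
    for i, ya in enumerate(years):
        for yb in years[i + 1:]:
            both = wide[[ya, yb]].dropna()
            if len(both) < min_overlap:
                continue
            r = float(np.corrcoef(both[ya], both[yb])[0, 1])
            rows.append((ya, yb, len(both), r))
    table = pd.DataFrame(rows, columns=["year_a", "year_b", "n_common", "r"])
    if table.empty:
        warnings.warn(f"no year pair shares >= {min_overlap} accessions; "
                      "mean correlation undefined", stacklevel=2)
        return YearPairCorrelations(table=table, mean_r=float("nan"), n_pairs=0)
    return YearPairCorrelations(table=table, mean_r=float(table["r"].mean()),
                                n_pairs=len(table))


def origin_table(study: list[StudyRow] | dict[str, StudyRow],
                 max_origins: int = 22) -> pd.DataFrame:
    """Frequency table of accessions by origin (country string), descending.

    Origins past rank ``max_origins`` are collapsed into one
    ``"Others (k origins)"`` row; a ``Total`` row closes the table.
    Percentages are of the total and sum to 100 up to rounding.
    """
    if isinstance(study, dict):
        rows = list(study.values())
    else:
        rows = list(study)
    if not rows:
        return pd.DataFrame(columns=["origin", "n", "percent"])
    counts = pd.Series([r.country for r in rows]).value_counts()
    counts = counts.sort_values(ascending=False)
    total = int(counts.sum())

    head = counts.iloc[:max_origins]
    tail = counts.iloc[max_origins:]
    out = [(origin, int(n), round(100.0 * n / total, 1))
           for origin, n in head.items()]
    if len(tail) > 0:
        out.append((f"Others ({len(tail)} origins)", int(tail.sum()),
                    round(100.0 * tail.sum() / total, 1)))
    out.append(("Total", total, 100.0))
    return pd.DataFrame(out, columns=["origin", "n", "percent"])
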