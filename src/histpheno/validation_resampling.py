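"""Resampling studies: bias under structured missingness and split-half
precision of the BLUEs.

The bias study starts from a *balanced* accession x year grid extracted from a
dataset and deletes data under three scenarios:

* **S1_random** — every accession independently keeps a random subset of
  ``n_years_kept`` years (ignorable missingness);
* **S2_random_clusters** — accessions are partitioned at random into
  ``n_groups`` clusters and each cluster keeps one shared random year set;
* **S3_origin_groups** — like S2 but the clusters are the provided origin
  groups (collection-place blocks), emulating genebank entry cohorts.

For each of ``runs`` draws the variance-component model and the BLUE model are
refitted on the subsample; relative bias (estimate - balanced) / balanced is
computed for the genetic and mean error variance, and the subsample BLUEs are
regressed on the balanced-data BLUEs (intercept, slope, R^2).

Split-half precision randomly halves a dataset at the record (plot) level,
fits the BLUE model in each half and correlates the BLUEs of the accessions
present in both halves.

One master seed drives everything; per-run seeds are spawned with
``numpy.random.SeedSequence`` so each run is individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import Habit, HistoricalDataset, Trait, records_frame
from .errors import DegenerateDesignError, HistphenoError, UsageError
from . import mm_engine
from .mm_engine import ModelSpec

SCENARIOS = ("S1_random", "S2_random_clusters", "S3_origin_groups")


@dataclass
class BalancedSet:
    """A complete accession x year grid of (replicate-averaged) values."""

    accessions: list[str]
    years: list[int]
    values: np.ndarray  # shape (A, Y), no missing cells
    trait: Trait
    habit: Habit

    @property
    def A(self) -> int:
        return len(self.accessions)

    @property
    def Y(self) -> int:
        return len(self.years)

    def to_dataset(self, keep: np.ndarray | None = None) -> HistoricalDataset:
        """Materialize (a masked subset of) the grid as a dataset."""
        if keep is None:
            keep = np.ones_like(self.values, dtype=bool)
        ai, yi = np.nonzero(keep)
        rows = [(self.accessions[a], self.years[y], self.values[a, y])
                for a, y in zip(ai, yi)]
        return HistoricalDataset(trait=self.trait, habit=self.habit,
                                 records=records_frame(rows))


def extract_balanced(dataset: HistoricalDataset,
                     years: Sequence[int]) -> BalancedSet:
    """Accessions observed in *every* listed year (replicates averaged first)."""
    years = sorted(int(y) for y in years)
    missing_years = set(years) - set(dataset.years)
    if missing_years:
        raise UsageError(f"years absent from the dataset: {sorted(missing_years)}")
    wide = dataset.cell_means()[years].dropna()
    if wide.empty:
        raise HistphenoError("no accession has records in every requested year")
    return BalancedSet(
        accessions=list(wide.index),
        years=years,
        values=wide.to_numpy(float),
        trait=dataset.trait,
        habit=dataset.habit,
    )


@dataclass
class ScenarioSample:
    """One missing-data draw: each accession keeps exactly n_years_kept years."""

    scenario: str
    keep: np.ndarray  # boolean (A, Y)
    seed: int
    n_points: int


def sample_scenario(
    bal: BalancedSet,
    scenario: str,
    n_years_kept: int = 3,
    n_groups: int = 10,
    groups: Mapping[str, object] | None = None,
    seed: int = 0,
) -> ScenarioSample:
    """Draw one missingness pattern from the balanced grid under a scenario."""
    if scenario not in SCENARIOS:
        raise UsageError(f"scenario must be one of {SCENARIOS}, got {scenario!r}")
    if n_years_kept > bal.Y:
        raise UsageError("n_years_kept exceeds the number of balanced years")
    rng = np.random.default_rng(seed)
    keep = np.zeros((bal.A, bal.Y), dtype=bool)

    if scenario == "S1_random":
        for a in range(bal.A):
            keep[a, rng.choice(bal.Y, size=n_years_kept, replace=False)] = True
    else:
        if scenario == "S2_random_clusters":
            if n_groups > bal.A:
                raise UsageError("more clusters than accessions")
            cluster = rng.permutation(np.arange(bal.A) % n_groups)
        else:  # S3_origin_groups
            if groups is None:
                raise UsageError("S3_origin_groups requires a groups mapping")
            labels = [groups[a] for a in bal.accessions]
            _, cluster = np.unique(labels, return_inverse=True)
        for c in np.unique(cluster):
            year_set = rng.choice(bal.Y, size=n_years_kept, replace=False)
            keep[np.ix_(cluster == c, year_set)] = True

    assert (keep.sum(axis=1) == n_years_kept).all()
    return ScenarioSample(scenario=scenario, keep=keep, seed=seed,
                          n_points=int(keep.sum()))


@dataclass
class BiasStats:
    """Bias statistics of one resampling run."""

    rel_bias_G: float
    rel_bias_e: float
    intercept: float
    slope: float
    r2: float
    n_points: int


def relative_bias(estimate: float, reference: float) -> float:
    """(d_hat - d) / d."""
    return (estimate - reference) / reference


@dataclass
class BiasStudyResult:
    runs: pd.DataFrame  # one row of BiasStats per converged run
    n_failed: int
    scenario: str

    def summary(self) -> pd.Series:
        return self.runs[["rel_bias_G", "rel_bias_e", "intercept", "slope",
                          "r2"]].mean()


def _fit_pair(dataset: HistoricalDataset, min_year_n: int):
    """Variance-component fit + BLUE fit of one dataset."""
    vc_fit = mm_engine.fit(dataset, ModelSpec.variance_components(min_year_n))
    blue_fit = mm_engine.fit(dataset, ModelSpec.blue_model(min_year_n))
    return vc_fit, mm_engine.blues(blue_fit)


def bias_study(
    bal: BalancedSet,
    scenario: str,
    runs: int = 100,
    seed: int = 0,
    *,
    n_years_kept: int = 3,
    n_groups: int = 10,
    groups: Mapping[str, object] | None = None,
    min_year_n: int = 3,
) -> BiasStudyResult:
    """Relative bias of variance components and BLUE regression across
    ``runs`` subsampling draws under one missingness scenario.

    The reference values are the fits of the full balanced grid.  Runs whose
    fits do not converge are recorded and excluded from the summaries.
    """
    full = bal.to_dataset()
    ref_vc, ref_blues = _fit_pair(full, min_year_n)
    ref_series = pd.Series(ref_blues)

    child_seeds = np.random.SeedSequence(seed).generate_state(runs) % (2**31 - 1)
    rows = []
    n_failed = 0
    for run, run_seed in enumerate(child_seeds):
        sample = sample_scenario(bal, scenario, n_years_kept, n_groups,
                                 groups, seed=int(run_seed))
        sub = bal.to_dataset(sample.keep)
        try:
            vc_fit, sub_blues = _fit_pair(sub, min_year_n)
        except DegenerateDesignError:
            n_failed += 1
            continue
        if not vc_fit.converged:
            n_failed += 1
            continue
        sub_series = pd.Series(sub_blues)
        common = ref_series.index.intersection(sub_series.index)
        reg = stats.linregress(ref_series[common], sub_series[common])
        rows.append({
            "run": run,
            "rel_bias_G": relative_bias(vc_fit.varcomp.sigma2_G,
                                        ref_vc.varcomp.sigma2_G),
            "rel_bias_e": relative_bias(vc_fit.varcomp.sigma2_e_bar,
                                        ref_vc.varcomp.sigma2_e_bar),
            "intercept": float(reg.intercept),
            "slope": float(reg.slope),
            "r2": float(reg.rvalue) ** 2,
            "n_points": sample.n_points,
        })
    return BiasStudyResult(runs=pd.DataFrame(rows), n_failed=n_failed,
                           scenario=scenario)


@dataclass
class SplitHalfResult:
    per_run: pd.DataFrame  # run, r, n_common
    mean_r: float
    mean_n_common: float
    n_failed: int


def split_half_precision(
    dataset: HistoricalDataset,
    runs: int = 100,
    seed: int = 0,
    *,
    min_year_n: int = 3,
) -> SplitHalfResult:
    """Precision of the BLUEs by repeated record-level half-splitting.

    Each run randomly splits the records into two equally sized halves, fits
    the BLUE model in each, and correlates the BLUEs of the accessions present
    in both halves.  Accessions with a single record fall into one half only
    and drop out of that run's correlation.
    """
    n = dataset.n_records
    if n < 4:
        raise UsageError("dataset too small to split")
    child_seeds = np.random.SeedSequence(seed).generate_state(runs) % (2**31 - 1)
    rows = []
    n_failed = 0
    spec = ModelSpec.blue_model(min_year_n)
    for run, run_seed in enumerate(child_seeds):
        rng = np.random.default_rng(int(run_seed))
        perm = rng.permutation(n)
        in_first = np.zeros(n, dtype=bool)
        in_first[perm[: n // 2]] = True
        try:
            b1 = pd.Series(mm_engine.blues(mm_engine.fit(dataset.subset(in_first), spec)))
            b2 = pd.Series(mm_engine.blues(mm_engine.fit(dataset.subset(~in_first), spec)))
        except DegenerateDesignError:
            n_failed += 1
            continue
        common = b1.index.intersection(b2.index)
        if len(common) < 3:
            n_failed += 1
            continue
        r = float(np.corrcoef(b1[common], b2[common])[0, 1])
        rows.append({"run": run, "r": r, "n_common": len(common)})
    per_run = pd.DataFrame(rows)
    return SplitHalfResult(
        per_run=per_run,
        mean_r=float(per_run["r"].mean()) if len(per_run) else float("nan"),
        mean_n_common=float(per_run["n_common"].mean()) if len(per_run) else float("nan"),
        n_failed=n_failed,
    )
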