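"""Synthetic unbalanced historical phenotype datasets with known ground truth.

The generator emulates the statistical structure of seed-regeneration records
from a genebank: an additive genotype + year model with year-specific error
variances, strongly unbalanced occupancy (accessions observed in only a few
of the available years), a small fraction (~1%) of accession-years with two
plots, block-structured (non-random) missingness driven by genebank entry
cohorts, and optional gross-outlier contamination.

The default preset is "spring flowering-time like": grand mean 60 days,
genetic variance 27, year variance 49 and per-year error variances drawn
uniformly in [9, 25] (squared days).  Every generated value is exactly
recomputable from the returned :class:`SimulationTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


import numpy as np
import pandas as pd

from .datatypes import Habit, HistoricalDataset, StudyRow, Trait
from .errors import HistphenoError

_MAX_MASK_RETRIES = 100


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the generator; defaults are the spring-FT-like preset."""

    n_genotypes: int = 200
    n_years: int = 10
    mu: float = 60.0
    sigma2_G: float = 27.0
    sigma2_Y: float = 49.0
    sigma2_e_range: tuple[float, float] = (9.0, 25.0)
    missingness: str = "random"  # random | cohort_blocks | origin_blocks
    occupancy: float = 0.4
    dup_rate: float = 0.01
    outlier_rate: float = 0.0
    outlier_shift_sd: float = 10.0
    n_origins: int = 30
    regen_interval: int = 3
    cohort_width: int = 2
    start_year: int = 1946
    trait: Trait = Trait.FT
    habit: Habit = Habit.SPRING
    seed: int = 0

    def __post_init__(self):
        if self.sigma2_G < 0 or self.sigma2_Y < 0 or min(self.sigma2_e_range) < 0:
            raise HistphenoError("variances must be non-negative")
        if not (0.0 < self.occupancy <= 1.0):
            raise HistphenoError("occupancy must be in (0, 1]")
        if not (0.0 <= self.dup_rate < 1.0):
            raise HistphenoError("dup_rate must be in [0, 1)")
        if self.missingness not in ("random", "cohort_blocks", "origin_blocks"):
            raise HistphenoError(f"unknown missingness {self.missingness!r}")


@dataclass
class SimulationTruth:
    """Everything needed to recompute the generated values exactly."""

    params: SimulationParams
    genotype_effects: pd.Series  # accession_id -> g_i
    year_effects: pd.Series  # year -> u_y
    sigma2_e_by_year: pd.Series  # year -> error variance
    records: pd.DataFrame  # per-record: error, shift, outlier flag
    origins: pd.Series  # accession_id -> origin label

    def analytic_h2(self, e_bar: float) -> float:
        """Entry-mean heritability implied by the generating parameters at an
        average of ``e_bar`` test years per genotype."""
        s2g = self.params.sigma2_G
        s2e = float(self.sigma2_e_by_year.mean())
        return s2g / (s2g + s2e / e_bar)

    def recompute_value(self, accession_id: str, year: int, error: float,
                        shift: float) -> float:
        return (self.params.mu + self.genotype_effects[accession_id]
                + self.year_effects[year] + error + shift)


def cohort_mask(n_genotypes: int, n_years: int, cohort_width: int,
                regen_interval: int, seed: int) -> np.ndarray:
    """Block-structured occupancy: genotypes enter the collection in cohorts
    and are regenerated every ``regen_interval`` years from their entry year.

    Cohorts are contiguous runs of genotypes whose entry years advance by
    ``cohort_width``; entry years wrap within the year range so every cohort
    gets at least one observed year.  Returns a boolean
    (n_genotypes, n_years) array.
    """
    if cohort_width < 1 or regen_interval < 1:
        raise HistphenoError("cohort_width and regen_interval must be >= 1")
    rng = np.random.default_rng(seed)
    n_cohorts = max(1, int(np.ceil(n_genotypes * cohort_width / max(n_years, 1))))
    cohort_of = rng.integers(0, n_cohorts, size=n_genotypes)
    entry_year = (cohort_of * cohort_width) % n_years
    mask = np.zeros((n_genotypes, n_years), dtype=bool)
    years = np.arange(n_years)
    for g in range(n_genotypes):
        mask[g, (years >= entry_year[g]) & ((years - entry_year[g]) % regen_interval == 0)] = True
    return mask


def _origin_labels(params: SimulationParams, rng: np.random.Generator,
                   n: int) -> np.ndarray:
    """Long-tailed categorical origin labels (Zipf-like weights)."""
    k = params.n_origins
    labels = np.array([f"Origin-{i + 1:02d}" for i in range(k)])
    weights = 1.0 / np.arange(1, k + 1) ** 1.1
    weights /= weights.sum()
    return rng.choice(labels, size=n, p=weights)


def _occupancy_mask(params: SimulationParams, rng: np.random.Generator,
                    origins: np.ndarray) -> np.ndarray:
    ng, ny = params.n_genotypes, params.n_years
    if params.missingness == "random":
        mask = rng.random((ng, ny)) < params.occupancy
        for g in range(ng):
            retries = 0
            while not mask[g].any():
                mask[g] = rng.random(ny) < params.occupancy
                retries += 1
                if retries > _MAX_MASK_RETRIES:
                    raise HistphenoError(
                        f"occupancy {params.occupancy} too low to populate "
                        f"genotype {g} within {_MAX_MASK_RETRIES} retries"
                    )
        return mask
    if params.missingness == "cohort_blocks":
        return cohort_mask(ng, ny, params.cohort_width, params.regen_interval,
                           int(rng.integers(0, 2**31 - 1)))
    # origin_blocks: all accessions of one origin share a year block
    mask = np.zeros((ng, ny), dtype=bool)
    years = np.arange(ny)
    for origin in np.unique(origins):
        members = np.where(origins == origin)[0]
        entry = int(rng.integers(0, ny))
        keep = (years >= entry) & ((years - entry) % params.regen_interval == 0)
        mask[np.ix_(members, np.where(keep)[0])] = True
    return mask


def simulate_dataset(params: SimulationParams) -> tuple[HistoricalDataset, SimulationTruth]:
    """Draw one dataset under the additive genotype + year model.

    value = mu + g_i + u_y + e_iyr (+ contamination shift), with
    g ~ N(0, sigma2_G), u ~ N(0, sigma2_Y) and e ~ N(0, sigma2_e,y) where the
    per-year error variances are drawn uniformly in ``sigma2_e_range``.

    Returns the dataset together with a :class:`SimulationTruth` from which
    every value can be recomputed bit-exactly.
    """
    rng = np.random.default_rng(params.seed)
    ng, ny = params.n_genotypes, params.n_years
    acc_ids = np.array([f"HOR{g + 1:05d}" for g in range(ng)])
    years = np.arange(params.start_year, params.start_year + ny)

    g_eff = rng.normal(0.0, np.sqrt(params.sigma2_G), size=ng)
    u_eff = rng.normal(0.0, np.sqrt(params.sigma2_Y), size=ny)
    lo, hi = params.sigma2_e_range
    s2e = rng.uniform(lo, hi, size=ny) if hi > lo else np.full(ny, float(lo))

    origins = _origin_labels(params, rng, ng)
    mask = _occupancy_mask(params, rng, origins)

    gi, yi = np.nonzero(mask)
    # ~dup_rate of occupied accession-years get a second plot
    dup = rng.random(len(gi)) < params.dup_rate
    gi = np.concatenate([gi, gi[dup]])
    yi = np.concatenate([yi, yi[dup]])
    order = np.lexsort((yi, gi))
    gi, yi = gi[order], yi[order]

    errors = rng.normal(0.0, np.sqrt(s2e[yi]))
    shifts = np.zeros(len(gi))
    outlier = np.zeros(len(gi), dtype=bool)
    if params.outlier_rate > 0:
        outlier = rng.random(len(gi)) < params.outlier_rate
        signs = rng.choice([-1.0, 1.0], size=len(gi))
        shifts[outlier] = (signs * params.outlier_shift_sd * np.sqrt(s2e[yi]))[outlier]

    values = params.mu + g_eff[gi] + u_eff[yi] + errors + shifts
    df = pd.DataFrame({
        "accession_id": acc_ids[gi],
        "harvest_year": years[yi],
        "value": values,
    })
    df["replicate_index"] = df.groupby(["accession_id", "harvest_year"]).cumcount() + 1

    sow = "20.03" if params.habit == Habit.SPRING else "05.10"
    study = {}
    first_year = df.groupby("accession_id")["harvest_year"].min()
    for i, acc in enumerate(acc_ids):
        fy = int(first_year[acc])
        study[acc] = StudyRow(
            accession_id=acc,
            accession_number=f"BAR {i + 1}",
            sowing_date=f"{sow}.{fy}",
            harvest_year=fy,
            country=str(origins[i]),
            comment="",
        )

    dataset = HistoricalDataset(trait=params.trait, habit=params.habit,
                                records=df, study=study)
    truth = SimulationTruth(
        params=params,
        genotype_effects=pd.Series(g_eff, index=acc_ids),
        year_effects=pd.Series(u_eff, index=years),
        sigma2_e_by_year=pd.Series(s2e, index=years),
        records=pd.DataFrame({
            "accession_id": df["accession_id"],
            "harvest_year": df["harvest_year"],
            "replicate_index": df["replicate_index"],
            "error": errors,
            "shift": shifts,
            "outlier": outlier,
        }),
        origins=pd.Series(origins, index=acc_ids),
    )
    return dataset, truth


def ft_spring_preset(**overrides) -> SimulationParams:
    """The spring flowering-time-like preset, optionally overridden."""
    return replace(SimulationParams(), **overrides)
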