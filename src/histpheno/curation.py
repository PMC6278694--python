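"""Outlier screening and dataset enhancement.

The procedure is a single detect -> remove -> refit pass:

1. fit the BLUE model (genotypes fixed, years random, year-specific error
   variances);
2. standardize each conditional residual by the fitted error standard
   deviation of its year stratum;
3. rescale the standardized residuals robustly: subtract their median and
   divide by 1.4826 x MAD (the normal-consistent median absolute deviation);
4. convert to two-sided standard-normal p-values and apply the step-down
   Bonferroni-Holm procedure at family-wise level alpha (default 0.05);
5. remove the flagged records and refit the BLUE model on the enhanced data.

Flagged records are removed, never corrected or imputed.  The family of tests
is one trait x growth-habit dataset; families are never pooled across traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import HistoricalDataset
from .errors import DegenerateDesignError, UsageError
from . import mm_engine
from .mm_engine import FitResult, ModelSpec

#: normal-consistency constant: 1.4826 * MAD estimates a Gaussian SD
MAD_CONSTANT = 1.4826


def standardize_residuals(fit: FitResult) -> np.ndarray:
    """Conditional residuals divided by the fitted error SD of their year
    stratum.

    Requires a heteroscedastic fit (each record's year stratum carries its own
    error variance).  Strata whose variance was floored produce a warning and
    large-but-finite standardized values.
    """
    if not fit.spec.heteroscedastic_errors:
        warnings.warn("fit has a single pooled error variance; standardization "
                      "is homoscedastic", stacklevel=2)
    floored = [s for s, flag in fit.varcomp.boundary.items()
               if flag and s in fit.varcomp.sigma2_e_by_stratum]
    if floored:
        warnings.warn(
            f"error stratum/strata {floored} at the variance floor; their "
            "standardized residuals are not informative", stacklevel=2)
    return fit.residuals / np.sqrt(fit.sigma2_e_by_record)


def madr_rescale(z: np.ndarray) -> tuple[np.ndarray, bool]:
    """Median-center and MAD-rescale a residual vector.

    Returns ``((z - median) / (1.4826 * MAD), degenerate)``.  When the MAD is
    zero no record can be scored against the others: the rescaled values are
    all zero and ``degenerate`` is True, so downstream flags nothing.
    """
    z = np.asarray(z, float)
    if z.size < 2:
        raise UsageError("madr_rescale needs at least 2 values")
    med = np.median(z)
    mad = np.median(np.abs(z - med))
    if mad == 0.0:
        return np.zeros_like(z), True
    return (z - med) / (MAD_CONSTANT * mad), False


def holm_flag(p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Step-down Bonferroni-Holm rejections at family-wise level ``alpha``."""
    p = np.asarray(p, float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise UsageError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="holm")
    return reject


@dataclass
class OutlierReport:
    """Outcome of one detect -> remove -> refit pass.

    ``table`` has one row per input record with its residual diagnostics and
    Holm decision; ``enhanced`` is the input dataset minus flagged records.
    ``fit_initial`` is the screening fit, ``fit_enhanced`` the refit on the
    enhanced data (None when the refit preconditions fail; see
    ``refit_error``).
    """

    table: pd.DataFrame
    alpha: float
    n_flagged: int
    enhanced: HistoricalDataset
    fit_initial: FitResult
    fit_enhanced: FitResult | None
    degenerate_spread: bool = False
    refit_error: str | None = None

    @property
    def blues(self) -> dict[str, float]:
        """Final BLUEs from the enhanced-data refit."""
        if self.fit_enhanced is None:
            raise UsageError(f"enhanced-data refit unavailable: {self.refit_error}")
        return mm_engine.blues(self.fit_enhanced)


def drop_sparse_years(dataset: HistoricalDataset, n_min: int) -> tuple[HistoricalDataset, pd.DataFrame]:
    """Remove all records of years carrying fewer than ``n_min`` records.

    This reproduces the manual exclusion of convergence-breaking sparse years
    (e.g. a year with only two plant-height plots) as an explicit curation
    step; the readers themselves never drop data.
    """
    counts = dataset.records["harvest_year"].value_counts()
    sparse = counts[counts < n_min].index
    keep = ~dataset.records["harvest_year"].isin(sparse)
    dropped = dataset.records[~keep].copy()
    return dataset.subset(keep), dropped


def detect_and_enhance(
    dataset: HistoricalDataset,
    alpha: float = 0.05,
    *,
    min_year_n: int = 3,
) -> OutlierReport:
    """Run the full two-step outlier procedure on one trait x habit dataset.

    Exactly one detection pass is performed (no iteration to convergence).
    Conservation holds by construction: input records = enhanced records +
    flagged records.
    """
    spec = ModelSpec.blue_model(min_year_n=min_year_n)
    fit_initial = mm_engine.fit(dataset, spec)

    z = standardize_residuals(fit_initial)
    rescaled, degenerate = madr_rescale(z)
    if degenerate:
        p = np.ones_like(rescaled)
    else:
        p = 2.0 * stats.norm.sf(np.abs(rescaled))
    flags = holm_flag(p, alpha)

    table = dataset.records[["accession_id", "harvest_year", "replicate_index",
                             "value"]].copy()
    table["residual"] = fit_initial.residuals
    table["standardized_residual"] = z
    table["rescaled_residual"] = rescaled
    table["p_value"] = p
    table["outlier"] = flags

    enhanced = dataset.subset(~flags)
    fit_enhanced = None
    refit_error = None
    try:
        fit_enhanced = mm_engine.fit(enhanced, spec)
    except DegenerateDesignError as exc:
        refit_error = str(exc)
        warnings.warn(f"enhanced-data refit failed: {exc}", stacklevel=2)

    return OutlierReport(
        table=table,
        alpha=alpha,
        n_flagged=int(flags.sum()),
        enhanced=enhanced,
        fit_initial=fit_initial,
        fit_enhanced=fit_enhanced,
        degenerate_spread=degenerate,
        refit_error=refit_error,
    )
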