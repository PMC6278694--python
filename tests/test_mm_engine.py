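"""REML engine checks against independent oracles.

The oracles here never touch the engine's mixed-model-equation path: the
restricted log-likelihood is recomputed from the explicit n x n covariance
matrix, BLUEs from an explicit GLS solve with a *different* (sum-to-zero)
coding, variance components from the closed-form balanced one-way ANOVA, and
an external reference fit from R nlme (frozen in conftest).
"""

import numpy as np
import pytest
from scipy import linalg

from histpheno import mm_engine
from histpheno.datatypes import HistoricalDataset, records_frame
from histpheno.errors import DegenerateDesignError, UsageError
from histpheno.mm_engine import ModelSpec, VarianceComponents, blues, fit, reml_loglik

from conftest import NLME_REFERENCE


# ---------------------------------------------------------------------------
# explicit-covariance oracle (independent of the MME identity)
# ---------------------------------------------------------------------------

def vform_reml_loglik(dataset, spec, sigma2_G, sigma2_Y, sigma2_e_by_year):
    """REML loglik via V = ZGZ' + R built explicitly; brute force O(n^3)."""
    df = dataset.records
    y = df["value"].to_numpy(float)
    n = len(y)
    accs = sorted(df["accession_id"].unique())
    years = sorted(df["harvest_year"].unique())
    ZG = (df["accession_id"].to_numpy()[:, None] == np.array(accs)).astype(float)
    ZY = (df["harvest_year"].to_numpy()[:, None] == np.array(years)).astype(float)

    V = np.diag(df["harvest_year"].map(sigma2_e_by_year).to_numpy(float))
    cols = [np.ones((n, 1))]
    if spec.genotype_role == "random":
        V += sigma2_G * ZG @ ZG.T
    else:
        cols.append(ZG[:, 1:])
    if spec.year_role == "random":
        V += sigma2_Y * ZY @ ZY.T
    else:
        cols.append(ZY[:, 1:])
    X = np.hstack(cols)
    p = X.shape[1]
    Vi = linalg.inv(V)
    XVX = X.T @ Vi @ X
    P = Vi - Vi @ X @ linalg.inv(XVX) @ X.T @ Vi
    return -0.5 * ((n - p) * np.log(2 * np.pi) + np.linalg.slogdet(V)[1]
                   + np.linalg.slogdet(XVX)[1] + y @ P @ y)


def gls_estimable_means(dataset, sigma2_Y, sigma2_e_by_year):
    """BLUEs by explicit GLS with sum-to-zero genotype coding (years random)."""
    df = dataset.records
    y = df["value"].to_numpy(float)
    n = len(y)
    accs = sorted(df["accession_id"].unique())
    years = sorted(df["harvest_year"].unique())
    ZG = (df["accession_id"].to_numpy()[:, None] == np.array(accs)).astype(float)
    ZY = (df["harvest_year"].to_numpy()[:, None] == np.array(years)).astype(float)
    # sum-to-zero: columns for all but the last genotype, last coded -1
    S = ZG[:, :-1] - ZG[:, [-1]]
    X = np.hstack([np.ones((n, 1)), S])
    V = np.diag(df["harvest_year"].map(sigma2_e_by_year).to_numpy(float))
    V += sigma2_Y * ZY @ ZY.T
    Vi = linalg.inv(V)
    beta = linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    effects = np.concatenate([beta[1:], [-beta[1:].sum()]])
    return dict(zip(accs, beta[0] + effects))


# ---------------------------------------------------------------------------
# likelihood definition and optimality
# ---------------------------------------------------------------------------

def test_reml_loglik_matches_explicit_covariance(toy6, nlme_dataset):
    """The MME-based loglik equals the explicit-V definition at several points."""
    cases = [
        (toy6, ModelSpec.variance_components(min_year_n=1), 4.0, 2.0),
        (toy6, ModelSpec.blue_model(min_year_n=1), None, 3.0),
        (nlme_dataset, ModelSpec.blue_model(min_year_n=1), None, 6.0),
        (nlme_dataset, ModelSpec.year_fixed(min_year_n=1), 5.0, None),
    ]
    for ds, spec, s2g, s2y in cases:
        s2e = {y: 1.0 + 0.5 * i for i, y in enumerate(ds.years)}
        vc = VarianceComponents(s2g, s2y, s2e)
        got = reml_loglik(ds, spec, vc)
        want = vform_reml_loglik(ds, spec, s2g, s2y, s2e)
        assert got == pytest.approx(want, abs=1e-9)


def test_fit_matches_grid_search_oracle():
    """On a 6-record toy with an interior optimum the engine beats a dense
    grid over (s2_G, s2_Y, s2_e1, s2_e2) and lands within one grid step of
    the grid argmax."""
    rows = [("g1", 2000, 15.33), ("g1", 2001, 14.87), ("g2", 2000, 9.02),
            ("g2", 2001, 11.59), ("g3", 2000, 15.79), ("g3", 2001, 19.44)]
    ds = HistoricalDataset("FT", "spring", records_frame(rows))
    spec = ModelSpec.variance_components(min_year_n=1)
    f = fit(ds, spec)
    assert f.converged
    assert not any(f.varcomp.boundary.values())

    vary = float(np.var(ds.records["value"], ddof=1))
    grid = np.geomspace(0.02 * vary, 3.0 * vary, 16)
    step = grid[1] / grid[0]
    years = ds.years
    best_ll, best = -np.inf, None
    for a in grid:
        for b in grid:
            for c in grid:
                for d in grid:
                    ll = vform_reml_loglik(ds, spec, a, b, {years[0]: c, years[1]: d})
                    if ll > best_ll:
                        best_ll, best = ll, (a, b, c, d)

    assert f.reml_loglik >= best_ll - 1e-9
    est = (f.varcomp.sigma2_G, f.varcomp.sigma2_Y,
           f.varcomp.sigma2_e_by_year[years[0]],
           f.varcomp.sigma2_e_by_year[years[1]])
    for e, g in zip(est, best):
        assert g / step <= e <= g * step


def test_fitted_optimum_beats_random_perturbations(nlme_dataset):
    """Loglik at the fitted point >= loglik at 50 perturbed parameter points."""
    spec = ModelSpec.blue_model(min_year_n=1)
    f = fit(nlme_dataset, spec)
    rng = np.random.default_rng(0)
    for _ in range(50):
        vc = VarianceComponents(
            None,
            f.varcomp.sigma2_Y * rng.uniform(0.5, 2.0),
            {y: v * rng.uniform(0.5, 2.0)
             for y, v in f.varcomp.sigma2_e_by_year.items()},
        )
        assert reml_loglik(nlme_dataset, spec, vc) <= f.reml_loglik + 1e-9


def test_matches_nlme_reference_fit(nlme_dataset):
    """Engine reproduces the frozen R nlme varIdent fit of the same model."""
    f = fit(nlme_dataset, ModelSpec.blue_model(min_year_n=1))
    ref = NLME_REFERENCE
    # both are REML optima of the same likelihood; ours may be >= nlme's
    assert f.reml_loglik >= ref["loglik"] - 1e-4
    assert f.reml_loglik == pytest.approx(ref["loglik"], abs=5e-3)
    assert f.varcomp.sigma2_Y == pytest.approx(ref["sigma2_Y"], rel=0.01)
    for year, v in ref["sigma2_e"].items():
        assert f.varcomp.sigma2_e_by_year[year] == pytest.approx(v, rel=0.02, abs=1e-3)
    b = blues(f)
    for acc, v in ref["blues"].items():
        assert b[acc] == pytest.approx(v, abs=2e-3)


def test_balanced_one_way_matches_anova_closed_form():
    """Genotype-random fit on a balanced one-year design reproduces
    sigma2_e = MSE and sigma2_G = (MSG - MSE)/r to 1e-6 relative."""
    rng = np.random.default_rng(7)
    g = {"a": -3.0, "b": 0.0, "c": 2.0, "d": 4.0}
    reps = 3
    rows = [(gi, 2000, 50 + g[gi] + rng.normal(0, 1.5))
            for gi in g for _ in range(reps)]
    ds = HistoricalDataset("FT", "spring", records_frame(rows))
    f = fit(ds, ModelSpec("random", "fixed", True, 1))

    df = ds.records
    grand = df["value"].mean()
    gm = df.groupby("accession_id")["value"].mean()
    msg = reps * ((gm - grand) ** 2).sum() / (len(g) - 1)
    mse = ((df["value"] - df["accession_id"].map(gm)) ** 2).sum() / (len(df) - len(g))
    assert f.varcomp.sigma2_e_bar == pytest.approx(mse, rel=1e-6)
    assert f.varcomp.sigma2_G == pytest.approx((msg - mse) / reps, rel=1e-6)


def test_em_loglik_monotone_every_iteration(toy6, nlme_dataset):
    for ds in (toy6, nlme_dataset):
        f = fit(ds, ModelSpec.variance_components(min_year_n=1),
                method="em", max_iter=60)
        diffs = np.diff(f.loglik_path)
        assert (diffs >= -1e-9).all()


def test_scale_equivariance(nlme_dataset):
    """Scaling the data by c scales every fitted variance by c^2 and shifts
    no structure (centering leaves variances untouched)."""
    spec = ModelSpec.variance_components(min_year_n=1)
    f1 = fit(nlme_dataset, spec)
    c = 3.0
    scaled = nlme_dataset.records.copy()
    scaled["value"] = scaled["value"] * c + 100.0
    f2 = fit(HistoricalDataset("FT", "spring", scaled), spec)
    assert f2.varcomp.sigma2_G == pytest.approx(c**2 * f1.varcomp.sigma2_G, rel=1e-4)
    assert f2.varcomp.sigma2_Y == pytest.approx(c**2 * f1.varcomp.sigma2_Y, rel=1e-4)
    for y in nlme_dataset.years:
        assert f2.varcomp.sigma2_e_by_year[y] == pytest.approx(
            c**2 * f1.varcomp.sigma2_e_by_year[y], rel=1e-3, abs=1e-8)


# ---------------------------------------------------------------------------
# BLUEs
# ---------------------------------------------------------------------------

def test_noiseless_balanced_blues_equal_row_means(noiseless_dataset):
    f = fit(noiseless_dataset, ModelSpec.blue_model(min_year_n=1))
    rowmeans = noiseless_dataset.records.groupby("accession_id")["value"].mean()
    for acc, v in blues(f).items():
        assert v == pytest.approx(rowmeans[acc], abs=1e-6)
    # noiseless: every error variance at the floor
    assert all(f.varcomp.boundary[s] for s in f.varcomp.sigma2_e_by_stratum)


def test_blues_match_gls_oracle_with_different_coding(nlme_dataset):
    """At the fitted variances, BLUEs equal an explicit GLS solve using
    sum-to-zero coding: the reported means are coding-invariant."""
    f = fit(nlme_dataset, ModelSpec.blue_model(min_year_n=1))
    oracle = gls_estimable_means(nlme_dataset, f.varcomp.sigma2_Y,
                                 f.varcomp.sigma2_e_by_year)
    b = blues(f)
    for acc in oracle:
        assert b[acc] == pytest.approx(oracle[acc], abs=1e-8)


def test_blues_invariant_to_record_order(nlme_dataset):
    f1 = fit(nlme_dataset, ModelSpec.blue_model(min_year_n=1))
    perm = nlme_dataset.records.sample(frac=1.0, random_state=3).reset_index(drop=True)
    f2 = fit(HistoricalDataset("FT", "spring", perm), ModelSpec.blue_model(min_year_n=1))
    b1, b2 = blues(f1), blues(f2)
    for acc in b1:
        assert abs(b1[acc] - b2[acc]) <= 1e-9


def test_blues_invariant_to_reference_level(nlme_dataset):
    """Renaming accessions so the internal reference level changes does not
    change any reported adjusted mean."""
    renamed = nlme_dataset.records.copy()
    mapping = {a: f"zz_{a}" if a == "g1" else a
               for a in renamed["accession_id"].unique()}
    renamed["accession_id"] = renamed["accession_id"].map(mapping)
    f1 = fit(nlme_dataset, ModelSpec.blue_model(min_year_n=1))
    f2 = fit(HistoricalDataset("FT", "spring", renamed), ModelSpec.blue_model(min_year_n=1))
    b1, b2 = blues(f1), blues(f2)
    for acc in b1:
        assert b1[acc] == pytest.approx(b2[mapping[acc]], abs=1e-8)


def test_blues_on_random_genotype_fit_is_usage_error(nlme_dataset):
    f = fit(nlme_dataset, ModelSpec.variance_components(min_year_n=1))
    with pytest.raises(UsageError, match="BLUP"):
        blues(f)


# ---------------------------------------------------------------------------
# degenerate designs and bookkeeping
# ---------------------------------------------------------------------------

def test_single_year_with_random_years_is_degenerate():
    rows = [("a", 2000, 1.0), ("b", 2000, 2.0), ("c", 2000, 3.0)]
    ds = HistoricalDataset("FT", "spring", records_frame(rows))
    with pytest.raises(DegenerateDesignError, match="single year"):
        fit(ds, ModelSpec.blue_model(min_year_n=1))


def test_empty_dataset_rejected():
    ds = HistoricalDataset("FT", "spring", records_frame([]))
    with pytest.raises(DegenerateDesignError):
        fit(ds, ModelSpec.blue_model())


def test_min_year_n_pools_sparse_years(sim_default):
    """Years below min_year_n share the pooled stratum; others keep their own."""
    ds, _ = sim_default
    counts = ds.records["harvest_year"].value_counts()
    f = fit(ds, ModelSpec.blue_model(min_year_n=int(counts.min()) + 1))
    pooled_years = [y for y, s in f.stratum_by_year.items()
                    if s == mm_engine.POOLED_STRATUM]
    assert counts.loc[pooled_years].lt(counts.min() + 1).all()
    assert len(set(f.stratum_by_year.values())) < len(counts) + 1


def test_e_bar_counts_distinct_years():
    rows = [("a", 2000, 1.0), ("a", 2000, 1.5), ("a", 2001, 2.0),
            ("b", 2000, 2.0), ("b", 2001, 2.5), ("b", 2001, 2.2),
            ("c", 2000, 3.0), ("c", 2001, 3.3)]
    ds = HistoricalDataset("FT", "spring", records_frame(rows))
    f = fit(ds, ModelSpec.variance_components(min_year_n=1))
    # a: 2 distinct years, b: 2, c: 2 -> E_bar = 2, despite duplicate plots
    assert f.E_bar == pytest.approx(2.0)


def test_residuals_align_with_records(nlme_dataset):
    f = fit(nlme_dataset, ModelSpec.blue_model(min_year_n=1))
    assert len(f.residuals) == nlme_dataset.n_records
    assert len(f.sigma2_e_by_record) == nlme_dataset.n_records
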