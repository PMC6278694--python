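"""Resampling studies: scenario structure, identity limits, unbiasedness under
random missingness, split-half precision and reproducibility."""

import numpy as np
import pytest

from histpheno.errors import UsageError
from histpheno.synthetic_data import SimulationParams, simulate_dataset
from histpheno.validation_resampling import (SCENARIOS, bias_study,
                                             extract_balanced, relative_bias,
                                             sample_scenario,
                                             split_half_precision)

from conftest import SEED


# ---------------------------------------------------------------------------
# balanced-set extraction
# ---------------------------------------------------------------------------

def test_extract_balanced_keeps_fully_observed_accessions():
    ds, _ = simulate_dataset(SimulationParams(
        n_genotypes=50, n_years=4, occupancy=0.7, dup_rate=0.0, seed=SEED))
    wide = ds.cell_means()
    fully = wide.dropna().index
    bal = extract_balanced(ds, ds.years)
    assert sorted(bal.accessions) == sorted(fully)
    assert bal.Y == 4
    assert np.isfinite(bal.values).all()


def test_extract_balanced_averages_replicates():
    ds, _ = simulate_dataset(SimulationParams(
        n_genotypes=40, n_years=3, occupancy=1.0, dup_rate=0.3, seed=SEED))
    bal = extract_balanced(ds, ds.years)
    cm = ds.cell_means()
    acc, yr = bal.accessions[0], bal.years[1]
    assert bal.values[0, 1] == pytest.approx(cm.loc[acc, yr])


def test_extract_balanced_unknown_year_errors(sim_default):
    ds, _ = sim_default
    with pytest.raises(UsageError, match="absent"):
        extract_balanced(ds, [1900])


# ---------------------------------------------------------------------------
# scenario sampling
# ---------------------------------------------------------------------------

def test_every_scenario_keeps_exact_point_count(balanced_400x6):
    bal, truth = balanced_400x6
    groups = truth.origins.to_dict()
    for scenario in SCENARIOS:
        s = sample_scenario(bal, scenario, n_years_kept=3, n_groups=10,
                            groups=groups, seed=SEED)
        assert s.n_points == 1200
        assert (s.keep.sum(axis=1) == 3).all()


def test_s2_partitions_all_accessions(balanced_400x6):
    bal, _ = balanced_400x6
    s = sample_scenario(bal, "S2_random_clusters", n_years_kept=3,
                        n_groups=10, seed=SEED)
    # each accession keeps exactly one shared 3-year set; cluster sizes sum to A
    year_sets = {tuple(np.where(row)[0]) for row in s.keep}
    assert len(year_sets) <= 10
    assert s.keep.shape[0] == 400


def test_keeping_all_years_returns_full_grid(balanced_400x6):
    bal, _ = balanced_400x6
    for scenario in ("S1_random", "S2_random_clusters"):
        s = sample_scenario(bal, scenario, n_years_kept=bal.Y, seed=SEED)
        assert s.keep.all()


def test_scenario_reproducible_from_seed(balanced_400x6):
    bal, _ = balanced_400x6
    a = sample_scenario(bal, "S1_random", seed=42)
    b = sample_scenario(bal, "S1_random", seed=42)
    assert np.array_equal(a.keep, b.keep)
    c = sample_scenario(bal, "S1_random", seed=43)
    assert not np.array_equal(a.keep, c.keep)


def test_s3_requires_groups(balanced_400x6):
    bal, _ = balanced_400x6
    with pytest.raises(UsageError, match="groups"):
        sample_scenario(bal, "S3_origin_groups", seed=SEED)


def test_s2_more_clusters_than_accessions(balanced_400x6):
    bal, _ = balanced_400x6
    with pytest.raises(UsageError):
        sample_scenario(bal, "S2_random_clusters", n_groups=401, seed=SEED)


# ---------------------------------------------------------------------------
# bias study
# ---------------------------------------------------------------------------

def _small_balanced(n_genotypes=60, n_years=6, seed=SEED):
    ds, truth = simulate_dataset(SimulationParams(
        n_genotypes=n_genotypes, n_years=n_years, occupancy=1.0,
        dup_rate=0.0, seed=seed))
    return extract_balanced(ds, ds.years), truth


def test_relative_bias_formula():
    assert relative_bias(1.1, 1.0) == pytest.approx(0.1)
    assert relative_bias(0.5, 1.0) == pytest.approx(-0.5)


def test_identity_subsample_has_zero_bias_and_unit_regression():
    """n_years_kept = Y removes nothing: rel_bias 0 and regression (0, 1, 1)."""
    bal, _ = _small_balanced()
    res = bias_study(bal, "S1_random", runs=5, seed=SEED, n_years_kept=bal.Y)
    assert res.n_failed == 0
    assert len(res.runs) == 5
    assert np.allclose(res.runs["rel_bias_G"], 0.0, atol=1e-8)
    assert np.allclose(res.runs["rel_bias_e"], 0.0, atol=1e-8)
    assert np.allclose(res.runs["intercept"], 0.0, atol=1e-6)
    assert np.allclose(res.runs["slope"], 1.0, atol=1e-8)
    assert np.allclose(res.runs["r2"], 1.0, atol=1e-10)


def test_random_missingness_is_unbiased():
    """S1 keeps years at random per accession: mean relative bias of the
    genetic variance stays within Monte-Carlo error of zero."""
    bal, _ = _small_balanced()
    res = bias_study(bal, "S1_random", runs=20, seed=SEED, n_years_kept=3)
    assert len(res.runs) + res.n_failed == 20
    rb = res.runs["rel_bias_G"]
    mc_margin = 3 * rb.std(ddof=1) / np.sqrt(len(rb)) + 0.02
    assert abs(rb.mean()) <= mc_margin
    # regression of subsample BLUEs on balanced BLUEs stays near identity
    assert res.runs["slope"].mean() == pytest.approx(1.0, abs=0.05)
    assert res.runs["r2"].min() > 0.7


def test_bias_study_runs_computed_for_clustered_scenarios(balanced_400x6):
    """S2/S3 statistics are computed (their sign/size is data-dependent)."""
    bal, truth = balanced_400x6
    res = bias_study(bal, "S2_random_clusters", runs=3, seed=SEED)
    assert len(res.runs) + res.n_failed == 3
    assert {"rel_bias_G", "rel_bias_e", "intercept", "slope", "r2"} <= set(res.runs)


# ---------------------------------------------------------------------------
# split-half precision
# ---------------------------------------------------------------------------

def test_split_half_noiseless_r_is_one(sim_noiseless):
    ds, _ = sim_noiseless
    with pytest.warns(UserWarning):  # error variances at the floor
        res = split_half_precision(ds, runs=5, seed=SEED)
    assert res.n_failed == 0
    assert np.allclose(res.per_run["r"], 1.0, atol=1e-6)


def test_split_half_reproducible(sim_default):
    ds, _ = sim_default
    a = split_half_precision(ds, runs=4, seed=9)
    b = split_half_precision(ds, runs=4, seed=9)
    assert a.per_run["r"].tolist() == b.per_run["r"].tolist()


def test_split_half_matches_reliability_approximation():
    """With k records per accession and heritability on the accession-mean
    scale, the expected half-vs-half BLUE correlation is approximately
    s2_G / (s2_G + 2 * s2_e_bar / k)."""
    params = SimulationParams(n_genotypes=150, n_years=8, occupancy=0.5,
                              sigma2_G=27.0, sigma2_Y=49.0,
                              sigma2_e_range=(16.0, 16.0), dup_rate=0.0,
                              seed=SEED)
    ds, _ = simulate_dataset(params)
    k = ds.records_per_accession().mean()
    expected = 27.0 / (27.0 + 2 * 16.0 / k)
    res = split_half_precision(ds, runs=20, seed=SEED)
    assert res.mean_r == pytest.approx(expected, abs=0.1)
    assert res.mean_n_common > 0.5 * len(ds.accessions)


def test_split_half_r_increases_with_heritability():
    """Precision rises with simulated heritability (3-point grid)."""
    means = []
    for s2g in (5.0, 27.0, 120.0):
        ds, _ = simulate_dataset(SimulationParams(
            n_genotypes=120, n_years=8, occupancy=0.5, sigma2_G=s2g,
            sigma2_e_range=(16.0, 16.0), dup_rate=0.0, seed=SEED))
        means.append(split_half_precision(ds, runs=8, seed=SEED).mean_r)
    assert means[0] < means[1] < means[2]
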