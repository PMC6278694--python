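"""Shared fixtures: small frozen toys and seeded synthetic datasets.

All fixtures are generated programmatically; the only literal data are tiny
frozen toys whose reference values were computed with independent oracles
(explicit-covariance GLS/REML brute force, closed-form ANOVA, and R's
nlme::lme with varIdent error weights).
"""

import numpy as np
import pytest

from histpheno.datatypes import HistoricalDataset, records_frame
from histpheno.synthetic_data import SimulationParams, simulate_dataset

#: master seed for every seeded test in the suite
SEED = 20180278


@pytest.fixture
def noiseless_dataset() -> HistoricalDataset:
    """Balanced, complete, noiseless 5 genotypes x 4 years; value = 10 + g + u."""
    g = {"a": -2.0, "b": 0.0, "c": 1.0, "d": 3.0, "e": 5.0}
    u = {2000: -1.0, 2001: 0.5, 2002: 2.0, 2003: -1.5}
    rows = [(gi, y, 10.0 + g[gi] + u[y]) for gi in g for y in u]
    return HistoricalDataset("FT", "spring", records_frame(rows))


@pytest.fixture
def toy6() -> HistoricalDataset:
    """Frozen 3 genotypes x 2 years toy (6 records, 4 variance parameters)."""
    rows = [("g1", 2000, 10.0), ("g1", 2001, 12.0), ("g2", 2000, 14.0),
            ("g2", 2001, 17.0), ("g3", 2000, 20.0), ("g3", 2001, 19.0)]
    return HistoricalDataset("FT", "spring", records_frame(rows))


# 23-record unbalanced fixture and its reference fit from R nlme::lme
# (value ~ genotype, random = ~1|year, weights = varIdent(~1|year), REML).
NLME_ROWS = [
    ("g1", 2000, 48.2383), ("g1", 2001, 54.6068), ("g1", 2002, 56.4844),
    ("g2", 2000, 51.654), ("g2", 2001, 52.819), ("g2", 2002, 54.1529),
    ("g3", 2001, 46.8003), ("g3", 2002, 49.7536),
    ("g4", 2000, 57.1256), ("g4", 2001, 57.5324), ("g4", 2002, 60.6982),
    ("g5", 2000, 45.4765), ("g5", 2001, 51.0134), ("g5", 2002, 52.7115),
    ("g6", 2000, 52.9148), ("g6", 2001, 54.4529), ("g6", 2002, 56.5244),
    ("g7", 2000, 46.6204), ("g7", 2001, 48.2719), ("g7", 2002, 50.5155),
    ("g8", 2000, 47.043), ("g8", 2001, 50.4388), ("g8", 2002, 53.7807),
]

NLME_REFERENCE = {
    "loglik": -28.36330326,
    "sigma2_Y": 6.09952100,
    "sigma2_e": {2000: 4.92442188, 2001: 0.45232623, 2002: 0.08737528},
    "blues": {
        "g1": 54.116152, "g2": 51.955597, "g3": 47.262180, "g4": 58.192934,
        "g5": 50.386702, "g6": 54.193158, "g7": 48.152621, "g8": 51.200964,
    },
}


@pytest.fixture
def nlme_dataset() -> HistoricalDataset:
    return HistoricalDataset("FT", "spring", records_frame(NLME_ROWS))


@pytest.fixture(scope="session")
def sim_default():
    """One draw of the default spring-FT-like preset (200 x 10, occupancy 0.4)."""
    return simulate_dataset(SimulationParams(seed=SEED))


@pytest.fixture(scope="session")
def sim_noiseless():
    """Additive genotype + year signal with (essentially) zero error variance."""
    params = SimulationParams(n_genotypes=60, n_years=8, occupancy=0.6,
                              sigma2_e_range=(1e-12, 1e-12), dup_rate=0.0,
                              seed=SEED)
    return simulate_dataset(params)


@pytest.fixture(scope="session")
def balanced_400x6():
    """Complete 400 accessions x 6 years grid, the bias-study geometry."""
    from histpheno.validation_resampling import extract_balanced
    ds, truth = simulate_dataset(SimulationParams(
        n_genotypes=400, n_years=6, occupancy=1.0, dup_rate=0.0, seed=SEED))
    return extract_balanced(ds, ds.years), truth
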