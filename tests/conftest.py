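from __future__ import annotations

import numpy as np
import pytest

from gradshift.fitting import build_design_matrix
from gradshift.model import GradientModel
from gradshift.simulate import TEST_POSITIONS, make_paper_fixture
from gradshift.stimuli import ExperimentDesign, ResponseTable, pair_records


@pytest.fixture(scope="session")
def paper_fixture():
    """One seeded simulation of all four study designs."""
    return make_paper_fixture(seed=123)


@pytest.fixture(scope="session")
def paper_pairs(paper_fixture):
    return pair_records(paper_fixture["records"])


@pytest.fixture
def differential_design():
    return ExperimentDesign(
        experiment_id="heptanal+/nonanal-",
        protocol="differential",
        cs_plus=7,
        cs_minus=9,
        test_positions=TEST_POSITIONS,
        n_ants=40,
    )


def simulate_count_tables(sigma, sigma_prime, cs_plus, cs_minus, n, rng,
                          positions=TEST_POSITIONS):
    """Binomial-count response tables drawn from the multiplicative model."""
    positions = np.asarray(positions, dtype=float)
    p_abs = np.exp(-((positions - cs_plus) ** 2) / (2 * sigma**2))
    model = GradientModel(sigma=sigma, sigma_prime=sigma_prime,
                          center_plus=cs_plus, center_minus=cs_minus)
    p_diff = np.asarray(model.response(positions)) / 100.0
    abs_table = ResponseTable(tuple(int(p) for p in positions), (n,) * len(positions),
                              tuple(int(k) for k in rng.binomial(n, p_abs)))
    diff_table = ResponseTable(tuple(int(p) for p in positions), (n,) * len(positions),
                               tuple(int(k) for k in rng.binomial(n, p_diff)))
    return abs_table, diff_table


def noise_free_xy(sigma, sigma_prime, cs_plus, cs_minus, positions=TEST_POSITIONS):
    """Exact (X, y) pairs from the multiplicative model, no sampling noise."""
    positions = np.asarray(positions, dtype=float)
    model = GradientModel(sigma=sigma, sigma_prime=sigma_prime,
                          center_plus=cs_plus, center_minus=cs_minus)
    y_abs = 100.0 * np.exp(-((positions - cs_plus) ** 2) / (2 * sigma**2))
    y_diff = np.asarray(model.response(positions))
    X = np.column_stack([np.tile(positions, 2), np.repeat([0.0, 1.0], len(positions))])
    return X, np.concatenate([y_abs, y_diff])
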