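"""Shared fixtures: the shipped-defaults LPS population used across tests.

The population is simulated once per session (500 cells, fixed seed) in the
fully heterogeneous and the NFkB-module-denoised configurations, together
with their dynamic-feature tables.
"""

import numpy as np
import pandas as pd
import pytest

from combisig import extract_features
from combisig.pathway_model import (PathwayParameters, PopulationSpec,
                                    simulate_cell, simulate_population,
                                    stimulus_program)

POPULATION_SEED = 11
N_CELLS = 500


@pytest.fixture(scope="session")
def representative_params():
    return PathwayParameters()


@pytest.fixture(scope="session")
def lps_program():
    return stimulus_program("LPS", 100.0)


@pytest.fixture(scope="session")
def lps_representative_sim(representative_params, lps_program):
    """Single representative-cell simulation with the full state trace."""
    return simulate_cell(representative_params, lps_program)


@pytest.fixture(scope="session")
def lps_population(representative_params, lps_program):
    spec = PopulationSpec(n_cells=N_CELLS, seed=POPULATION_SEED)
    return simulate_population(spec, lps_program, representative_params)


@pytest.fixture(scope="session")
def lps_population_denoised(representative_params, lps_program):
    spec = PopulationSpec(n_cells=N_CELLS, seed=POPULATION_SEED,
                          denoise=frozenset({"nfkb_module"}))
    return simulate_population(spec, lps_program, representative_params)


@pytest.fixture(scope="session")
def lps_features(lps_population):
    return extract_features(lps_population)


@pytest.fixture(scope="session")
def lps_features_denoised(lps_population_denoised):
    return extract_features(lps_population_denoised)


def paired_columns(features: pd.DataFrame) -> tuple[list, list]:
    """Matched (p38_*, nfkb_*) feature column lists."""
    a = [c for c in features.columns if c.startswith("p38_")]
    b = [c.replace("p38_", "nfkb_") for c in a]
    return a, b


def gaussian_classes(means, n_per_class, n_dims=2, sd=1.0, seed=0):
    """Labeled Gaussian blobs for estimator/classifier calibration tests."""
    rng = np.random.default_rng(seed)
    X, labels = [], []
    for i, mu in enumerate(means):
        mu = np.broadcast_to(np.atleast_1d(np.asarray(mu, float)), (n_dims,))
        X.append(rng.normal(mu, sd, size=(n_per_class, n_dims)))
        labels += [f"class_{i}"] * n_per_class
    return np.vstack(X), np.array(labels)
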