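"""Shared fixtures: synthetic worlds, toys, and trained imputers.

Expensive fixtures (the default-size world and imputers trained on it) are
session-scoped so the benchmark tests share one training run each.
"""

from __future__ import annotations

import numpy as np
import pytest

from panfill.imputer import ReactionImputer
from panfill.reactome import split_train_test
from panfill.synthetic import (
    SyntheticWorldConfig,
    generate_incidence,
    generate_metabolic_world,
    generate_toy_network,
)


@pytest.fixture(scope="session")
def small_world():
    """A fast, small clade-structured world for unit tests."""
    config = SyntheticWorldConfig(
        n_reactions=100, n_core=20, n_modules=8, module_size=5,
        n_clades=3, genomes_per_clade=10, seed=11,
    )
    matrix, info = generate_incidence(config)
    return matrix, info


@pytest.fixture(scope="session")
def default_world():
    """The default study-size world: 400 reactions, 6 clades x 40 genomes."""
    config = SyntheticWorldConfig(seed=1)
    matrix, info = generate_incidence(config)
    world = generate_metabolic_world(matrix, info)
    train_matrix, test_matrix = split_train_test(matrix)
    return {
        "config": config,
        "matrix": matrix,
        "info": info,
        "world": world,
        "train": train_matrix,
        "test": test_matrix,
        "train_pan": train_matrix.recompute_pan().pan_reactome,
    }


@pytest.fixture(scope="session")
def trained_imputer(default_world):
    """Imputer trained on the default world with uniform corruption."""
    imputer = ReactionImputer(random_state=7)
    imputer.fit(default_world["train"])
    return imputer


@pytest.fixture(scope="session")
def rare_trained_imputer(default_world):
    """Imputer trained with rare-biased corruption on the same data."""
    imputer = ReactionImputer(deletion_kind="rare_biased", random_state=7)
    imputer.fit(default_world["train"])
    return imputer


@pytest.fixture()
def linear_chain_toy():
    return generate_toy_network("linear_chain", size=4)


@pytest.fixture()
def branched_toy():
    return generate_toy_network("branched_cheap_expensive")


@pytest.fixture()
def parallel_toy():
    return generate_toy_network("parallel_paths")
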