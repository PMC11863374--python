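"""Shared fixtures: synthetic planted libraries at the study conditions.

The expensive fixtures (full leave-one-out on the n=200 planted library, the
LOCO stress protocol) are session-scoped so each is computed once per run.
"""

import numpy as np
import pytest
from rdkit import RDLogger

from yieldmap.chemdata import build_combinatorial_dataset
from yieldmap.descriptors import featurize_dataset
from yieldmap.evaluation import loco_evaluate, loo_evaluate
from yieldmap.modeling import ModelConfig
from yieldmap.synthetic import (
    generate_panels,
    loco_stress_fixture,
    make_planted_model,
    plant_and_label,
)

RDLogger.DisableLog("rdApp.*")


@pytest.fixture(scope="session")
def planted_library():
    """n=200 combinatorial library labeled by a 40-bit planted model, sigma=3."""
    azoles, amines = generate_panels(20, 10, seed=7)
    dataset = build_combinatorial_dataset(azoles, amines)
    planted = make_planted_model(dataset, seed=11)
    labeled, _ = plant_and_label(dataset, planted)
    return labeled, planted


@pytest.fixture(scope="session")
def planted_features(planted_library):
    labeled, planted = planted_library
    return featurize_dataset(labeled, "rdk")


@pytest.fixture(scope="session")
def planted_loo(planted_library, planted_features):
    """Full leave-one-out of Bayesian ridge on the planted library."""
    labeled, _ = planted_library
    preds, report = loo_evaluate(
        planted_features, labeled.yields, ModelConfig("bayesian_ridge")
    )
    return preds, report


@pytest.fixture(scope="session")
def stress_loco():
    """LOCO over azoles and amines on the unseen-motif stress library."""
    dataset, planted = loco_stress_fixture(seed=1)
    config = ModelConfig("bayesian_ridge")
    azole_results = loco_evaluate(dataset, "rdk", config, "azole")
    amine_results = loco_evaluate(dataset, "rdk", config, "amine")
    return dataset, planted, azole_results, amine_results


@pytest.fixture(scope="session")
def small_library():
    """20-record labeled library for fast shape/consistency tests."""
    azoles, amines = generate_panels(5, 4, seed=3)
    dataset = build_combinatorial_dataset(azoles, amines)
    planted = make_planted_model(
        dataset, n_active=12, seed=3, fingerprint_length=512
    )
    labeled, _ = plant_and_label(dataset, planted)
    return labeled


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
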