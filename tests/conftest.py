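"""Shared fixtures.

The trained-model fixtures are session-scoped because CPU training of even the
small networks takes minutes; every test that needs a trained segmenter or
u-map generator shares the same run.  All randomness is seeded, so the suite
is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

import ctfree_gfr as cg
from ctfree_gfr import models

TRAIN_SEED = 101
EVAL_SEED = 202

#: Small CPU training profile used across the suite: more, smaller steps and a
#: higher initial rate than the clinical profile so the small nets converge in
#: about a dozen epochs.
DESK_TRAIN = dict(batch_size=2, learning_rate=3e-3, seed=0)


@pytest.fixture(scope="session")
def desk_spec() -> cg.PhantomSpec:
    return cg.PhantomSpec.desk()


@pytest.fixture(scope="session")
def train_cases(desk_spec):
    """50 mixed-category phantom cases; train() splits them 8:1:1."""
    return cg.sample_population(50, seed=TRAIN_SEED, base_spec=desk_spec)


@pytest.fixture(scope="session")
def eval_cases(desk_spec):
    """10 held-out phantom cases never seen by any training split."""
    return cg.sample_population(10, seed=EVAL_SEED, base_spec=desk_spec)


@pytest.fixture(scope="session")
def window_norm() -> cg.NormalizationSpec:
    return cg.NormalizationSpec(method="windowing_maximum", window_upper=0.5)


@pytest.fixture(scope="session")
def trained_segmenter(train_cases, window_norm) -> models.TrainedModel:
    """Residual+attention 3-class segmenter trained on the 40-case split."""
    ncfg = models.NetworkConfig.for_segmentation(
        n_classes=3, initial_neurons=8, depth=2, block="residual", attention=True
    )
    data = models.make_segmentation_dataset(train_cases, window_norm, 3)
    tcfg = models.TrainConfig.desk(epochs=12, loss="GDSC", **DESK_TRAIN)
    net = models.build_network(ncfg, seed=0)
    return models.train(net, data, tcfg, normalization=window_norm,
                        network_config=ncfg)


@pytest.fixture(scope="session")
def trained_generator(train_cases) -> models.TrainedModel:
    """Two-window-input u-map generator trained on the same 40-case split."""
    ncfg = models.NetworkConfig.for_mumap(
        initial_neurons=8, depth=2, block="conventional", attention=False
    )
    data = models.make_mumap_dataset(train_cases)
    tcfg = models.TrainConfig.desk(epochs=12, loss="MAE", **DESK_TRAIN)
    net = models.build_network(ncfg, seed=0)
    return models.train(
        net, data, tcfg,
        normalization=cg.NormalizationSpec(method="log_maximum"),
        network_config=ncfg,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
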