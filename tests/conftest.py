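"""Shared fixtures: phantom cohorts and (expensive) trained models.

Training fixtures are session-scoped so the desk-scale stage-1 and
two-stage runs are paid for once and shared between the trained-behavior
unit tests and the acceptance suite. All problem sizes here are the
package's desk preset scaled to a 16-voxel grid.
"""

from __future__ import annotations

import numpy as np
import pytest

from morphldm.autoencoder import MorphAutoencoder
from morphldm.diffusion import LatentDiffusionModel
from morphldm.phantoms import default_spec, make_cohort

GRID = (16, 16, 16)
STAGE1_KW = dict(channels=(8, 16, 16), epochs=40, batch_size=8, lr=2e-3,
                 random_state=0)


@pytest.fixture(scope="session")
def spec16():
    return default_spec(GRID)


@pytest.fixture(scope="session")
def clean_spec16():
    """Noise- and smoothing-free variant: labels recoverable exactly."""
    return default_spec(GRID, noise_sd=0.0, smoothing_sigma=0.0)


@pytest.fixture(scope="session")
def cohort64(spec16):
    return make_cohort(spec16, 64, seed=1)


@pytest.fixture(scope="session")
def heldout50(spec16):
    return make_cohort(spec16, 50, seed=99)


@pytest.fixture(scope="session")
def trained_ae(cohort64):
    """Unconditional stage-1 model trained on the desk cohort."""
    return MorphAutoencoder(**STAGE1_KW).fit(cohort64)


@pytest.fixture(scope="session")
def conditional_pipeline(cohort64):
    """Conditional-variant stage 1 + stage 2 trained end to end."""
    ae = MorphAutoencoder(conditional=True, **STAGE1_KW).fit(cohort64)
    Z = ae.transform(cohort64, sample=True, random_state=11)
    dm = LatentDiffusionModel(T=100, channels=(16, 32, 32), n_steps=800,
                              batch_size=16, lr=2e-3, random_state=0)
    dm.fit(Z, conditions=[p.condition for p in cohort64])
    return ae, dm


@pytest.fixture(scope="session")
def toy_dm():
    """Diffusion model trained on scalar latents from N(2, 0.5^2)."""
    rng = np.random.default_rng(0)
    Z = rng.normal(2.0, 0.5, size=(256, 1, 1, 1, 1))
    dm = LatentDiffusionModel(T=100, channels=(8, 16, 16), n_steps=3000,
                              batch_size=32, lr=2e-3, random_state=0)
    dm.fit(Z, conditions=np.zeros((256, 2)))
    return dm


@pytest.fixture(scope="session")
def cohort120(spec16):
    return make_cohort(spec16, 120, seed=2)


@pytest.fixture(scope="session")
def age_predictor(cohort120):
    from morphldm.evaluation import ConditionPredictorCNN
    return ConditionPredictorCNN("age", n_steps=400, random_state=0).fit(cohort120)


@pytest.fixture(scope="session")
def sex_predictor(cohort120):
    from morphldm.evaluation import ConditionPredictorCNN
    return ConditionPredictorCNN("sex", n_steps=400, random_state=0).fit(cohort120)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
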