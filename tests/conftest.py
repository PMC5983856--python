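"""Shared fixtures: small phantom cohorts and a trained exemplar model.

Everything is generated programmatically and seeded; the session-scoped
model keeps the slow training step out of individual tests.
"""

import numpy as np
import pytest

from nodulesig import (FeatureConfig, PhantomSpec, generate_cohort,
                       generate_phantom, train_exemplar_model)


@pytest.fixture(scope="session")
def small_cohort():
    cohort, manifest = generate_cohort(8, seed=101)
    return cohort


@pytest.fixture(scope="session")
def model(small_cohort):
    """A nine-class exemplar model trained on a small phantom cohort."""
    return train_exemplar_model(small_cohort, n_vois=300, target_k=9, seed=202)


@pytest.fixture()
def solid_spec():
    """A noiseless fully solid nodule on an isotropic 1 mm grid."""
    return PhantomSpec(grid_shape=(34, 34, 34), spacing=(1.0, 1.0, 1.0),
                       nodule_center=(17, 17, 17), nodule_radius=5.0,
                       solid_core_radius=5.0, noise_sd=0.0, rng_seed=7)


@pytest.fixture()
def solid_truth(solid_spec):
    return generate_phantom(solid_spec)
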