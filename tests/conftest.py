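"""Shared fixtures: the phantom-population atlas, a trained shape model,
and the expensive multi-phantom studies reused across test modules."""

import numpy as np
import pytest

from wmlseg.experiments import (build_study_atlas, parameter_recovery_study,
                                shape_ablation_study,
                                train_study_shape_model)
from wmlseg.fit import FitConfig, fit_parameters
from wmlseg.phantom import PhantomSpec, generate_phantom

RECOVERY_SEEDS = list(range(300, 320))     # 20 zero-bias phantoms
ABLATION_SEEDS = list(range(200, 215))     # 15 low-load phantoms


@pytest.fixture(scope="session")
def study_atlas():
    return build_study_atlas(seed=0)


@pytest.fixture(scope="session")
def shape_model():
    return train_study_shape_model(seed=0)


@pytest.fixture(scope="session")
def recovery_records(study_atlas):
    """20 seeded zero-bias phantom fits with recovery diagnostics."""
    return parameter_recovery_study(study_atlas, RECOVERY_SEEDS)


@pytest.fixture(scope="session")
def ablation(study_atlas, shape_model):
    """Two-arm (shape prior vs f=1) study on 15 low-load phantoms."""
    return shape_ablation_study(study_atlas, shape_model, ABLATION_SEEDS)


@pytest.fixture(scope="session")
def default_fit(study_atlas):
    """One fitted default phantom (with lesions and bias) for inference tests."""
    image, labels, lesions, _bias, truth = generate_phantom(
        PhantomSpec(seed=7), 7)
    fr = fit_parameters(image, study_atlas, FitConfig(seed=7))
    return {"fit": fr, "labels": labels, "lesions": lesions, "truth": truth}
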