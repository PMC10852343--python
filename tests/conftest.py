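import dataclasses

import numpy as np
import pytest

from drgquant import SceneSpec, generate_section
from drgquant.scene_params import pipeline_config_for_scene

TINY_KW = dict(
    image_size=(448, 448), tissue_fraction=0.45,
    n_neurons_small=10, n_neurons_large=5, n_immune=3,
    n_tcells=3, n_cd3_only=2, n_nonneuronal_nuclei=5,
)


def tiny_spec(seed=0, **overrides) -> SceneSpec:
    kw = {**TINY_KW, **overrides}
    return SceneSpec(seed=seed, **kw)


@pytest.fixture(scope="session")
def noiseless_scene():
    """One small noiseless section with its config: (spec, stack, truth, cfg)."""
    spec = tiny_spec(seed=42, noise_sd=0.0)
    stack, truth = generate_section(spec)
    return spec, stack, truth, pipeline_config_for_scene(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
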