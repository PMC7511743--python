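import numpy as np
import pytest

from wmhmap import synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """A 600-subject synthetic cohort with one hypertension effect blob."""
    cfg = synthetic.GeneratorConfig(
        n_subjects=600, seed=11, grid_dims=(12, 12, 6),
        effect_blobs=[synthetic.EffectBlob("hypertension", (6, 6, 3), 3.0, 0.8)])
    table, stack, truth = synthetic.generate_cohort(cfg, with_stack=True)
    return cfg, table, stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
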