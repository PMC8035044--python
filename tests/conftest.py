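import numpy as np
import pytest

from lgnbinoc import synthetic_data as sd
from lgnbinoc.config import PipelineConfig


@pytest.fixture(scope="session")
def small_experiment():
    """Two strongly driven units, three conditions, 12 trials each."""
    pop = [
        sd.archetype_config("M"),
        sd.archetype_config("P", supp_gamma=0.5, supp_c50_nd=0.3,
                            supp_release_c50=0.4),
    ]
    design = sd.ExperimentDesign(
        contrasts_dom=[0.12, 0.9], contrasts_nondom=[0.0, 0.9],
        trials_per_condition=12)
    spikes, trials, truth = sd.simulate_experiment(pop, design, seed=101)
    return pop, design, spikes, trials, truth


@pytest.fixture
def fast_config():
    return PipelineConfig(seed=3, n_shuffles=200, n_boot=500)
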