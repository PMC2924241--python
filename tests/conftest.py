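import numpy as np
import pytest
from hypothesis import settings

from polywm.plasticity import PlasticityConfig
from polywm.protocols import prepare_wm_network, run_wm_trial
from polywm.toys import two_group_toy

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy():
    """Seven-neuron two-group toy: (network, red template, black template)."""
    return two_group_toy()


@pytest.fixture(scope="session")
def wm_setup():
    """Random network with 100 engineered groups (standard WM preparation)."""
    return prepare_wm_network(n_groups=100, network_seed=45, insert_seed=3)


@pytest.fixture(scope="session")
def wm_trial(wm_setup):
    """One cued-group working-memory trial (16 s) on the standard prep."""
    net, templates = wm_setup
    tpl = templates[3]
    res = run_wm_trial(net, [tpl], [0.0], duration=16_000.0,
                       plasticity=PlasticityConfig(), seed=3)
    return net, tpl, res


@pytest.fixture(scope="session")
def capacity_runs(wm_setup):
    """Simultaneous-cue trials at loads 1, 4 and 12 (13 s each)."""
    from polywm.protocols import capacity_experiment
    net, templates = wm_setup
    return capacity_experiment(net, templates, loads=[1, 4, 12],
                               duration=13_000.0, seed=20)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
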