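import warnings

import pytest

import juveri as jv


@pytest.fixture(scope="session")
def calf_spec():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return jv.packaged_specs("calf", seed=0)


@pytest.fixture(scope="session")
def piglet_spec():
    return jv.packaged_specs("piglet", seed=0)


@pytest.fixture(scope="session")
def calf_cohort(calf_spec):
    return jv.simulate_cohort(calf_spec, seed=0)


@pytest.fixture(scope="session")
def piglet_cohort(piglet_spec):
    return jv.simulate_cohort(piglet_spec, seed=0)
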