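import numpy as np
import pytest

from biofilm_electro.hh_membrane import (HHParams, StimulusProgram,
                                         make_variant, simulate_membrane)


@pytest.fixture(scope="session")
def hh_params():
    return HHParams()


@pytest.fixture(scope="session")
def working_stimulus():
    """Constant exposure at the working irradiance for the 60-min protocol."""
    return StimulusProgram.constant(15.99, 60.0)


@pytest.fixture(scope="session")
def variant_traces(hh_params, working_stimulus):
    """ThT traces for all four variants under the working stimulus."""
    out = {}
    for variant in ("wildtype", "delta_kch", "catalase", "ms_knockout"):
        params = make_variant(hh_params, variant)
        traj, trace = simulate_membrane(params, working_stimulus)
        out[variant] = (traj, trace)
    return out
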