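import numpy as np
import pytest

import nanopbtk as npk

#: times the calibration study sampled, plus the times quoted for curve
#: descriptors (21 h tracheobronchial, 28 h alveolar, 1454 h spleen residual)
OBS_TIMES = (4.0, 21.0, 24.0, 28.0, 168.0, 674.0, 1454.0)


@pytest.fixture(scope="session")
def params():
    return npk.default_parameters()


@pytest.fixture(scope="session")
def kreyling():
    return npk.kreyling_preset()


@pytest.fixture(scope="session")
def kreyling_result(params, kreyling):
    """One full-horizon simulation of the calibration scenario, shared."""
    return npk.run_simulation(params, kreyling.scenario, t_end=1500.0,
                              observation_times=OBS_TIMES)


@pytest.fixture(scope="session")
def kreyling_observables(kreyling_result):
    return {name: npk.extract_observable(kreyling_result,
                                         npk.DEFAULT_OBSERVABLES, name)
            for name in npk.DEFAULT_OBSERVABLES}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
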