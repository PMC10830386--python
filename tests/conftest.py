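import pytest

from vvcsim import default_parameters, run_all_levels, simulate


@pytest.fixture(scope="session")
def base_params():
    return default_parameters()


@pytest.fixture(scope="session")
def short_trace(base_params):
    """10 s of the calibrated baseline at 1 ms sampling."""
    return simulate(base_params, 10.0)


@pytest.fixture(scope="session")
def grid(base_params):
    """The full five-level occlusion experiment (3 min settle + 10 s ramp +
    5 s hold per level)."""
    return run_all_levels(base_params)
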