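import numpy as np
import pytest

from c4photo.parameters import ParameterSet, adjust_to_temperature, default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def adj25(params):
    return adjust_to_temperature(params, 25.0)


@pytest.fixture
def make_adjusted():
    def _make(T=25.0, **overrides):
        return adjust_to_temperature(ParameterSet(**overrides), T)

    return _make


def random_parameter_set(rng: np.random.Generator, alpha: float, f_cyc_scale: bool = True) -> ParameterSet:
    """Defaults perturbed by ±50%, for oracle-equivalence sweeps."""
    u = lambda: float(rng.uniform(0.5, 1.5))
    return ParameterSet(
        Vcmax25=40.0 * u(),
        Vpmax25=200.0 * u(),
        Vpr=80.0 * u(),
        Kc25=1210.0 * u(),
        Ko25=292.0 * u(),
        Kp25=82.0 * u(),
        gbs=0.003 * u(),
        Rd25=0.4 * u(),
        gamma_star25=(0.5 / 1310.0) * u(),
        f_cyc=0.3 * u() if f_cyc_scale else 0.3,
        alpha=alpha,
    )
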