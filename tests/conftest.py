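import numpy as np
import pytest

from rheomelt import (
    CarreauArrheniusParams,
    DrugShiftParams,
    SolubilityCurve,
    SweepDesign,
    generate_pure_polymer,
)

# Published Carreau-Arrhenius parameter sets for three pharmaceutical
# polymers at Tref = 160 °C: (eta0 Pa·s, gamma_c s^-1, c, EA).
POLYMER_PARAMS = {
    "bBMA": (1011.0, 26.8, 0.433, 122498.0),
    "SOL": (5146.0, 2.5, 0.363, 130846.0),
    "PVPVA": (18296.0, 1.0, 0.368, 184119.0),
}

TREF_C = 160.0


def params_for(name: str) -> CarreauArrheniusParams:
    return CarreauArrheniusParams.from_values(*POLYMER_PARAMS[name], TREF_C)


@pytest.fixture(scope="session")
def bbma_params() -> CarreauArrheniusParams:
    return params_for("bBMA")


@pytest.fixture(scope="session")
def sol_params() -> CarreauArrheniusParams:
    return params_for("SOL")


@pytest.fixture(scope="session")
def plasticizer() -> DrugShiftParams:
    return DrugShiftParams(s_plast=-6.0, s_filler=4.0)


@pytest.fixture(scope="session")
def rising_solubility() -> SolubilityCurve:
    # dissolved-limit line rising from 10 wt% at 130 °C to 35 wt% at 200 °C
    return SolubilityCurve(np.array([130.0, 200.0]), np.array([0.10, 0.35]))


@pytest.fixture(scope="session")
def bbma_clean_curves(bbma_params):
    """Noise-free triplicate oscillatory sweeps, 0.628-628 rad/s, 130-200 °C."""
    return generate_pure_polymer(SweepDesign(noise_sigma=0.0, seed=1), bbma_params)
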