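import numpy as np
import pytest

import coralcarb as cc

# published treatment structure used throughout the tests:
# (treatment pH_T, temperature degC) with salinity 35.5 assumed
TREATMENTS = [(8.09, 20.9), (7.81, 20.9), (7.63, 21.0)]
SALINITY = 35.5

# species-level delta11B regressions on seawater pH (slope, intercept)
D11B_REGRESSIONS = {"A_youngei": (2.37, 4.41), "P_damicornis": (4.37, -12.11)}


@pytest.fixture(scope="session")
def constants_ambient():
    """CO2-system constants at the ambient treatment (20.9 degC, S 35.5)."""
    return cc.equilibrium_constants(20.9, SALINITY)


@pytest.fixture(scope="session")
def synthetic_experiment():
    """One default synthetic experiment, shared across tests."""
    return cc.generate_experiment(cc.GeneratorParams(), seed=3)


def independent_co2_solver(pH, AT, T, S):
    """Brent root-finding solve of the alkalinity balance (oracle path).

    Treats DIC as the unknown and solves A_T(DIC; pH) = A_T numerically,
    independently of the package's closed-form inversion.
    """
    from scipy.optimize import brentq

    c = cc.equilibrium_constants(T, S)
    H = 10.0 ** (-pH)

    def alk_residual(dic):
        denom = H**2 + c.K1 * H + c.K1 * c.K2
        hco3 = dic * c.K1 * H / denom
        co3 = dic * c.K1 * c.K2 / denom
        borate = c.B_total / (1 + H / c.KB)
        return hco3 + 2 * co3 + borate + c.Kw / H - H - AT

    dic = brentq(alk_residual, 1e-9, 0.1, xtol=1e-15)
    denom = H**2 + c.K1 * H + c.K1 * c.K2
    co3 = dic * c.K1 * c.K2 / denom
    co2aq = dic * H**2 / denom
    return {
        "DIC": dic,
        "pCO2": co2aq / c.K0 * 1e6,
        "omega": co3 * c.Ca_total / c.Ksp_aragonite,
    }
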