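"""Shared fixtures and independent numerical oracles.

The oracles deliberately avoid the code paths they check: the normal CDF is
obtained by adaptive quadrature of the density, the chi-squared tail by
quadrature of its density, and binomial log-pmfs by explicit factorial
arithmetic.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

import choicebias as cb


def phi_oracle(x: float) -> float:
    """Standard normal CDF by numeric integration of the density."""
    if x < 0:
        return 1.0 - phi_oracle(-x)
    val, _ = quad(lambda s: math.exp(-0.5 * s * s) / math.sqrt(2 * math.pi),
                  0.0, x)
    return 0.5 + val


def chi2_sf_oracle(stat: float, df: int) -> float:
    """Upper chi-squared tail by numeric integration of the density."""
    def dens(u):
        return (u ** (df / 2 - 1) * math.exp(-u / 2)
                / (2 ** (df / 2) * math.gamma(df / 2)))
    val, _ = quad(dens, stat, np.inf)
    return val


def binom_logpmf_oracle(k: int, n: int, p: float) -> float:
    """Binomial log-pmf from explicit factorials."""
    coeff = math.factorial(n) // (math.factorial(k) * math.factorial(n - k))
    return math.log(coeff) + k * math.log(p) + (n - k) * math.log1p(-p)


@pytest.fixture
def phi():
    return phi_oracle


@pytest.fixture
def chi2_sf():
    return chi2_sf_oracle


@pytest.fixture
def binom_logpmf():
    return binom_logpmf_oracle


@pytest.fixture
def toy_table() -> pd.DataFrame:
    """Fixed 4-cell toy table: two orientations x two references, n=10 each."""
    rows = []
    for ref, theta, k in [("primary", -1.0, 2), ("primary", 1.0, 9),
                          ("mirrored", -1.0, 3), ("mirrored", 1.0, 7)]:
        for i in range(10):
            rows.append({"participant": "p1", "task": "symmetric",
                         "orientation_band": "horizontal", "reference": ref,
                         "orientation_deg": theta,
                         "response": 1 if i < k else 0})
    return pd.DataFrame(rows)


def make_symmetric_group(delta_s=0.0, delta_d=0.0, sigma=0.5, seed=0,
                         n_per_level=30, **lapses) -> pd.DataFrame:
    """One simulated symmetric-task group under the default design."""
    design = cb.DesignSpec(n_per_level_per_reference=n_per_level)
    params = cb.SymmetricParams(delta_s=delta_s, delta_d=delta_d,
                                sigma_primary=sigma, **lapses)
    return cb.simulate_group(design, "symmetric_sdt", params, seed=seed)


@pytest.fixture
def symmetric_group():
    return make_symmetric_group
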