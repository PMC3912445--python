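"""Shared fixtures and independent least-squares oracles.

The oracles here are deliberately written from the textbook normal
equations (moment sums for the line, Vandermonde solve for the parabola) so
they share no code path with the package's statsmodels-backed fits.
"""

import numpy as np
import pytest

import growthlaw as gl


def line_normal_equations(L, dL):
    """Simple-regression closed form: slope = Sxy/Sxx, intercept from means."""
    L = np.asarray(L, float)
    dL = np.asarray(dL, float)
    xbar, ybar = L.mean(), dL.mean()
    sxx = np.sum((L - xbar) ** 2)
    sxy = np.sum((L - xbar) * (dL - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = dL - (intercept + slope * L)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((dL - ybar) ** 2))
    return slope, intercept, ss_res, ss_tot


def quad_normal_equations(L, dL):
    """Solve (X'X) beta = X'y on the Vandermonde design [1, L, L^2]."""
    L = np.asarray(L, float)
    dL = np.asarray(dL, float)
    X = np.column_stack([np.ones_like(L), L, L**2])
    beta = np.linalg.solve(X.T @ X, X.T @ dL)
    resid = dL - X @ beta
    return beta, float(np.sum(resid**2))


@pytest.fixture
def herring_params():
    """Herring-scale parameters: k = 0.3 per year, L_max = 354 mm."""
    return gl.GrowthParams(k=0.3, L_max=354.0, unit="mm", step="year")


@pytest.fixture
def noiseless_table(herring_params):
    """Default synthetic table: 11 noiseless cohorts, ages 1-9."""
    return gl.generate_table(gl.SyntheticSpec(params=herring_params))


@pytest.fixture
def exact_line_pairs():
    """Pairs exactly on dL = -0.2 L + 10 (k = 0.2, L_max = 50)."""
    L = np.array([0.0, 10.0, 20.0, 30.0, 40.0])
    return gl.IncrementSet(L=L, dL=10.0 - 0.2 * L)
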