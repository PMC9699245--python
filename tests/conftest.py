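"""Shared fixtures and independent numerical oracles.

The tangent-construction oracle below never uses the closed-form
characteristic times from the package: the model curve is written out
directly, differentiated symbolically by sympy, and the inflection /
tangent intersections / half-conversion time are found by root
bracketing on dense grids.  It serves as the ground truth the
closed forms are checked against.
"""

from __future__ import annotations

import numpy as np
import pytest
import sympy as sp
from hypothesis import settings as hyp_settings
from scipy.optimize import brentq

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")

_t, _k, _rho = sp.symbols("t k rho", positive=True)
_f_expr = _rho * (sp.exp((1 + _rho) * _k * _t) - 1) / (
    1 + _rho * sp.exp((1 + _rho) * _k * _t)
)
_f = sp.lambdify((_t, _k, _rho), _f_expr, "numpy")
_d1 = sp.lambdify((_t, _k, _rho), sp.diff(_f_expr, _t), "numpy")
_d2 = sp.lambdify((_t, _k, _rho), sp.diff(_f_expr, _t, 2), "numpy")


def _bracket_root(fun, grid):
    vals = np.array([fun(t) for t in grid])
    sign = np.sign(vals)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if len(idx) == 0:
        raise RuntimeError("no sign change on bracketing grid")
    i = idx[0]
    return brentq(fun, grid[i], grid[i + 1], xtol=1e-300, rtol=1e-15)


def tangent_oracle(k: float, rho: float):
    """Numerically construct inflection, tangent and half times.

    Returns a dict with t_inflection, slope, t0_lag, t1_end,
    t_half_mid, t_half_f05 for the autocatalytic curve with rho < 1.
    """
    t_scale = 1.0 / ((1.0 + rho) * k)
    grid = t_scale * np.geomspace(1e-4, 60.0, 4000)
    t_infl = _bracket_root(lambda t: _d2(t, k, rho), grid)
    slope = float(_d1(t_infl, k, rho))
    f_infl = float(_f(t_infl, k, rho))
    t0 = t_infl - f_infl / slope
    t1 = t_infl + (1.0 - f_infl) / slope
    t_half = _bracket_root(lambda t: _f(t, k, rho) - 0.5, grid)
    return {
        "t_inflection": t_infl,
        "slope": slope,
        "t0_lag": t0,
        "t1_end": t1,
        "t_half_mid": 0.5 * (t0 + t1),
        "t_half_f05": t_half,
    }


@pytest.fixture
def clean_trace():
    """Noiseless sigmoid trace with known ground truth."""
    from fibrilkin import ThTTrace, autocatalytic_fraction

    truth = {"baseline": 100.0, "amplitude": 900.0, "k": 3e-3, "rho": 5e-3}
    t = np.arange(0.0, 6001.0, 60.0)
    s = truth["baseline"] + truth["amplitude"] * autocatalytic_fraction(
        t, truth["k"], truth["rho"]
    )
    return ThTTrace(time=t, signal=s, condition="control", replicate=0), truth
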