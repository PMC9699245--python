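"""Autocatalytic fibrillation kinetics for thioflavin-T (ThT) traces.

The fibrillar fraction of amyloid peptide is modelled by the
two-parameter autocatalytic rate law

    f(t) = rho * (exp[(1+rho) k t] - 1) / (1 + rho * exp[(1+rho) k t])

with f(0) = 0 and f -> 1 as t -> infinity.  ``k`` lumps nucleation and
elongation; ``rho`` is the dimensionless nucleation-to-overall ratio
k_n / k.  Given the monomer concentration ``a``, the elementary rate
constants follow as k_n = rho * k (s^-1) and k_e = k / a (M^-1 s^-1).

A raw ThT signal is fitted as signal(t) = F_bg + A_amp * f(t; k, rho),
i.e. baseline and amplitude are free parameters of the regression
rather than a pre-normalisation step, which keeps k and rho unbiased
by noisy endpoints.

Characteristic times are taken from the tangent at the inflection of
the fitted fraction curve: its intercept with f = 0 is the lag time
t_0, its intercept with the plateau f = 1 the end time t_1.  With
x = (1+rho) k t the closed forms are

    x_inflection = ln(1/rho)          f at inflection = (1-rho)/2
    x_0 = ln(1/rho) - 2(1-rho)/(1+rho)
    x_1 = ln(1/rho) + 2
    x(f=1/2) = ln((1+2 rho)/rho)

valid for rho < 1 (otherwise the inflection sits at negative time and
the trace is not sigmoidal).  Two half-aggregation times are reported:
the tangent midpoint (t_0 + t_1)/2 and the exact f = 0.5 solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Model

from .errors import DomainError, InputError

__all__ = [
    "ThTTrace",
    "AggregationFit",
    "DerivedTimes",
    "autocatalytic_fraction",
    "fit_trace",
    "decompose_rates",
    "derived_times",
    "characteristic_times",
    "half_time_midpoint",
    "endpoint_inhibition",
]

K_MAX = 10.0  # s^-1, upper fit bound
RHO_MAX = 10.0


@dataclass(frozen=True)
class ThTTrace:
    """One ThT fluorescence time course for a single condition/replicate.

    time is in seconds (strictly increasing), signal in arbitrary
    fluorescence units, monomer_concentration in molar.
    """

    time: np.ndarray
    signal: np.ndarray
    condition: str = ""
    replicate: int = 0
    monomer_concentration: float = 20e-6

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)
        if t.ndim != 1 or s.shape != t.shape:
            raise InputError("time and signal must be 1-D arrays of equal length")
        if t.size < 6:
            raise InputError(f"need >= 6 time points, got {t.size}")
        if not np.all(np.diff(t) > 0):
            raise InputError("time must be strictly increasing")
        if t[0] < 0:
            raise InputError("time must be nonnegative")
        if not np.all(np.isfinite(s)):
            raise InputError("signal contains non-finite values")
        if self.monomer_concentration <= 0:
            raise DomainError("monomer concentration must be positive")


@dataclass(frozen=True)
class AggregationFit:
    """Fitted parameters of the autocatalytic model for one trace."""

    baseline: float
    amplitude: float
    k: float
    rho: float
    k_n: float
    k_e: float
    monomer_concentration: float
    residual_sum_squares: float
    converged: bool
    message: str = ""
    stderr: dict[str, float | None] = field(default_factory=dict)

    def fraction(self, t):
        """Fitted fibrillar fraction f(t)."""
        return autocatalytic_fraction(t, self.k, self.rho)

    def model_signal(self, t):
        """Fitted signal curve baseline + amplitude * f(t)."""
        return self.baseline + self.amplitude * self.fraction(t)


@dataclass(frozen=True)
class DerivedTimes:
    """Tangent-construction characteristic times, in seconds.

    slope_at_inflection is df/dt (fraction per second).  t_half_mid is
    the midpoint (t0_lag + t1_end)/2; t_half_f05 solves f(t) = 0.5.
    """

    t_inflection: float
    slope_at_inflection: float
    t0_lag: float
    t1_end: float
    t_half_mid: float
    t_half_f05: float


def _check_k_rho(k: float, rho: float) -> None:
    if not (k > 0):
        raise DomainError(f"rate constant k must be positive, got {k}")
    if not (rho > 0):
        raise DomainError(f"rho must be positive, got {rho}")


def autocatalytic_fraction(t, k: float, rho: float):
    """Fibrillar fraction f(t) of the autocatalytic model.

    Evaluated in the overflow-free form
    f = rho (1 - e^{-x}) / (rho + e^{-x}) with x = (1+rho) k t, whose
    exponential only underflows for large x, so the plateau value 1 is
    returned exactly once x exceeds the floating-point range (~745 in
    natural-log units) instead of overflowing.

    Parameters
    ----------
    t : array_like
        Time in seconds, t >= 0.
    k : float
        Overall rate constant (s^-1), > 0.
    rho : float
        Nucleation-to-overall ratio k_n/k (dimensionless), > 0.
    """
    _check_k_rho(k, rho)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("time must be nonnegative")
    x = (1.0 + rho) * k * t
    with np.errstate(under="ignore"):
        e = np.exp(-x)
    f = rho * (1.0 - e) / (rho + e)
    if f.ndim == 0:
        return float(f)
    return f


def decompose_rates(k: float, rho: float, a: float) -> tuple[float, float]:
    """Split the overall rate constant into nucleation and elongation parts.

    Returns (k_n, k_e) with k_n = rho * k in s^-1 and k_e = k / a in
    M^-1 s^-1, a being the monomer concentration in molar.
    """
    _check_k_rho(k, rho)
    if not (a > 0):
        raise DomainError(f"monomer concentration must be positive, got {a}")
    return rho * k, k / a


def half_time_midpoint(t0_lag: float, t1_end: float) -> float:
    """Half-aggregation time as the midpoint of lag and end times."""
    return 0.5 * (t0_lag + t1_end)


def characteristic_times(k: float, rho: float) -> DerivedTimes:
    """Closed-form tangent-construction times for given (k, rho).

    Requires rho < 1: at rho >= 1 the inflection of the model curve
    falls at t <= 0 and the tangent construction is undefined.
    """
    _check_k_rho(k, rho)
    if rho >= 1:
        raise DomainError(
            f"rho={rho} >= 1: curve has no sigmoidal inflection at positive time"
        )
    c = (1.0 + rho) * k  # x = c * t
    x_infl = np.log(1.0 / rho)
    x0 = x_infl - 2.0 * (1.0 - rho) / (1.0 + rho)
    x1 = x_infl + 2.0
    x_half = np.log((1.0 + 2.0 * rho) / rho)
    t0, t1 = float(x0 / c), float(x1 / c)
    return DerivedTimes(
        t_inflection=float(x_infl / c),
        slope_at_inflection=k * (1.0 + rho) ** 2 / 4.0,
        t0_lag=t0,
        t1_end=t1,
        t_half_mid=half_time_midpoint(t0, t1),
        t_half_f05=float(x_half / c),
    )


def derived_times(fit: AggregationFit) -> DerivedTimes:
    """Characteristic times of a converged fit (see characteristic_times)."""
    if not fit.converged:
        raise InputError("derived times require a converged fit")
    return characteristic_times(fit.k, fit.rho)


def endpoint_inhibition(
    control_signal: float, sample_signal: float, blank: float | None = None
) -> float:
    """Percent inhibition from endpoint signals: 100 (C - S) / C.

    When a blank (negative control) is supplied it is subtracted from
    both signals first.  The result is not clipped; enhancement gives a
    negative percentage.
    """
    if blank is not None:
        control_signal = control_signal - blank
        sample_signal = sample_signal - blank
    if control_signal <= 0:
        raise DomainError("control signal must be positive after blank subtraction")
    return 100.0 * (control_signal - sample_signal) / control_signal


def _model_signal(t, baseline, amplitude, k, rho):
    return baseline + amplitude * autocatalytic_fraction(t, k, rho)


def _initial_guesses(trace: ThTTrace) -> dict[str, float]:
    """Heuristic starting values for the sigmoid regression.

    Baseline and amplitude from the signal range; the inflection is
    placed at the steepest finite-difference slope, k from the slope
    (df/dt ~ k/4 near small rho), and rho from one fixed-point pass of
    rho = exp(-(1+rho) k t_inflection) started at rho = 0.01.
    """
    t, s = trace.time, trace.signal
    baseline = float(np.min(s))
    amplitude = float(np.max(s) - np.min(s))
    slopes = np.diff(s) / np.diff(t)
    i = int(np.argmax(slopes))
    t_infl = 0.5 * (t[i] + t[i + 1])
    max_slope_frac = slopes[i] / amplitude if amplitude > 0 else 0.0
    k = 4.0 * max_slope_frac
    k = float(np.clip(k, 1e-12, K_MAX))
    rho = float(np.exp(-np.clip(1.01 * k * t_infl, 0.0, 700.0)))
    rho = float(np.clip(rho, 1e-12, RHO_MAX))
    return {"baseline": baseline, "amplitude": amplitude, "k": k, "rho": rho}


def fit_trace(trace: ThTTrace, init: dict[str, float] | None = None) -> AggregationFit:
    """Nonlinear least-squares fit of the autocatalytic model to a trace.

    Fits signal(t) = baseline + amplitude * f(t; k, rho) with all four
    parameters free (bounds: amplitude > 0, 0 < k <= 10 s^-1,
    0 < rho <= 10).  A flat or net-decreasing trace cannot constrain
    the model; it is reported as ``converged=False`` with a diagnostic
    message rather than raising.

    Parameters
    ----------
    trace : ThTTrace
    init : dict, optional
        Overrides for the automatic starting values; keys among
        {baseline, amplitude, k, rho}.
    """
    t, s = trace.time, trace.signal
    if t.size < 4:
        raise InputError("need at least as many points as parameters (4)")
    span = float(np.max(s) - np.min(s))
    failure = None
    if span <= 0:
        failure = "signal is constant; no aggregation transition to fit"
    elif s[-1] - s[0] <= 0:
        failure = "signal shows no net increase; trace is not sigmoidal"
    if failure is not None:
        return AggregationFit(
            baseline=float(np.mean(s)), amplitude=0.0, k=np.nan, rho=np.nan,
            k_n=np.nan, k_e=np.nan,
            monomer_concentration=trace.monomer_concentration,
            residual_sum_squares=float(np.sum((s - np.mean(s)) ** 2)),
            converged=False, message=failure,
        )

    guesses = _initial_guesses(trace)
    if init:
        guesses.update(init)

    model = Model(_model_signal, independent_vars=["t"])
    params = model.make_params(
        baseline={"value": guesses["baseline"]},
        amplitude={"value": max(guesses["amplitude"], 1e-12), "min": 1e-12},
        k={"value": guesses["k"], "min": 1e-12, "max": K_MAX},
        rho={"value": guesses["rho"], "min": 1e-12, "max": RHO_MAX},
    )
    result = model.fit(s, params, t=t)

    k = float(result.params["k"].value)
    rho = float(result.params["rho"].value)
    in_bounds = (1e-12 < k < K_MAX) and (1e-12 < rho < RHO_MAX)
    converged = bool(result.success) and in_bounds
    if converged:
        k_n, k_e = decompose_rates(k, rho, trace.monomer_concentration)
        message = "ok"
    else:
        k_n = k_e = np.nan
        message = "optimizer failed" if not result.success else \
            "fitted parameters pinned at bounds"
    stderr = {name: (None if p.stderr is None else float(p.stderr))
              for name, p in result.params.items()}
    return AggregationFit(
        baseline=float(result.params["baseline"].value),
        amplitude=float(result.params["amplitude"].value),
        k=k, rho=rho, k_n=k_n, k_e=k_e,
        monomer_concentration=trace.monomer_concentration,
        residual_sum_squares=float(np.sum(result.residual**2)),
        converged=converged, message=message, stderr=stderr,
    )
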