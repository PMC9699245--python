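"""Ellman-assay kinetics: initial rates, IC50, Lineweaver-Burk, mechanism.

Acetylcholinesterase activity is followed as the 412 nm absorbance of
TNB produced from DTNB and thiocholine.  Progress curves are reduced to
initial rates by ordinary least squares over an early linear window and
converted to uM/s by Beer-Lambert (default epsilon = 13,600 M^-1 cm^-1,
1 cm path).  Rates across inhibitor concentrations give dose-response
inhibition and a Hill-equation IC50; rates across substrate
concentrations give a double-reciprocal (Lineweaver-Burk) K_M / V_max
estimate, and comparing the inhibited with the free-enzyme fit yields a
mechanism call (competitive / noncompetitive / uncompetitive / mixed).

The double-reciprocal fit is deliberately unweighted least squares to
mirror how such plots are usually analysed in plate-reader practice;
``michaelis_menten_fit`` provides a direct nonlinear fit as an
independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import DomainError, InputError

__all__ = [
    "ProgressCurve",
    "RateEstimate",
    "DoseResponse",
    "IC50Fit",
    "MichaelisFit",
    "MechanismCall",
    "initial_rate",
    "dose_response",
    "fit_ic50",
    "lineweaver_burk",
    "michaelis_menten_fit",
    "classify_mechanism",
    "DEFAULT_EPSILON",
    "DEFAULT_MECHANISM_TOLERANCE",
]

# TNB chromophore at 412 nm; overridable wherever it is used.
DEFAULT_EPSILON = 13600.0  # M^-1 cm^-1
DEFAULT_PATH_CM = 1.0

# Relative tolerance separating "unchanged" from "shifted" K_M / V_max.
# 0.35 keeps a K_M shift of 0.15 -> 0.20 mM (ratio 1.33) classified as
# "little impact", the conventional reading for noncompetitive calls.
DEFAULT_MECHANISM_TOLERANCE = 0.35


@dataclass(frozen=True)
class ProgressCurve:
    """Absorbance-vs-time record for one assay well."""

    time: np.ndarray  # s, strictly increasing
    absorbance: np.ndarray  # AU at 412 nm
    substrate_mM: float = np.nan  # ATC concentration
    inhibitor_uM: float = 0.0
    condition: str = ""
    replicate: int = 0

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "absorbance", a)
        if t.ndim != 1 or a.shape != t.shape:
            raise InputError("time and absorbance must be 1-D arrays of equal length")
        if not np.all(np.diff(t) > 0):
            raise InputError("time must be strictly increasing")


@dataclass(frozen=True)
class RateEstimate:
    """Initial rate from the linear phase of a progress curve."""

    v: float  # uM/s
    slope_AU: float  # AU/s
    window: float  # s
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class DoseResponse:
    """Inhibition (%) as a function of inhibitor concentration (uM)."""

    concentration_uM: np.ndarray
    inhibition_pct: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.concentration_uM, dtype=float)
        i = np.asarray(self.inhibition_pct, dtype=float)
        object.__setattr__(self, "concentration_uM", c)
        object.__setattr__(self, "inhibition_pct", i)
        if c.shape != i.shape or c.ndim != 1:
            raise InputError("concentration and inhibition must be 1-D, equal length")


@dataclass(frozen=True)
class IC50Fit:
    """Hill-equation dose-response fit Inh = max * I^h / (ic50^h + I^h)."""

    ic50_uM: float
    hill_slope: float
    max_inhibition_pct: float
    residual_sum_squares: float
    indeterminate: bool = False
    interpolated: bool = False
    message: str = "ok"


@dataclass(frozen=True)
class MichaelisFit:
    """K_M / V_max from an unweighted double-reciprocal regression.

    K_M keeps the units of the substrate axis supplied (mM here);
    V_max is in uM/s.  slope = K_M/V_max and intercept = 1/V_max on the
    1/v vs 1/[S] axes.
    """

    K_M: float
    V_max: float
    intercept_1_over_vmax: float
    slope_km_over_vmax: float
    stderr: dict[str, float] = field(default_factory=dict)
    indeterminate: bool = False
    message: str = "ok"


@dataclass(frozen=True)
class MechanismCall:
    """Inhibition-mechanism classification from K_M / V_max ratios.

    Ratios are inhibited over free.  The label is a pure function of
    (km_ratio, vmax_ratio, tolerance): V_max down with K_M unchanged is
    noncompetitive; K_M up with V_max unchanged competitive; both down
    in proportion uncompetitive; anything else mixed.
    """

    label: str  # competitive|noncompetitive|uncompetitive|mixed|indeterminate
    vmax_ratio: float
    km_ratio: float
    tolerance: float


def initial_rate(
    curve: ProgressCurve,
    window: float = 120.0,
    epsilon: float = DEFAULT_EPSILON,
    path_cm: float = DEFAULT_PATH_CM,
) -> RateEstimate:
    """OLS slope of absorbance vs time over [t0, t0 + window], in uM/s.

    The slope in AU/s is converted via v = slope / (epsilon * l) * 1e6.
    A constant trace yields v = 0 with r_squared reported as 0.
    """
    if epsilon <= 0 or path_cm <= 0:
        raise DomainError("epsilon and path length must be positive")
    t, a = curve.time, curve.absorbance
    if window <= 0:
        raise InputError("window must be positive")
    span = t[-1] - t[0]
    if window > span and not np.isclose(window, span):
        raise InputError(f"window {window}s exceeds trace span {span:.6g}s")
    mask = t <= t[0] + window
    if mask.sum() < 5:
        raise InputError(f"need >= 5 points in rate window, got {int(mask.sum())}")
    res = stats.linregress(t[mask], a[mask])
    slope = float(res.slope)
    r2 = float(res.rvalue**2)
    if not np.isfinite(r2):  # zero-variance absorbance
        r2 = 0.0
    v = slope / (epsilon * path_cm) * 1e6
    return RateEstimate(
        v=v, slope_AU=slope, window=window, r_squared=r2, n_points=int(mask.sum())
    )


def dose_response(
    control: RateEstimate, per_concentration: dict[float, RateEstimate]
) -> DoseResponse:
    """Percent activity inhibition per inhibitor concentration.

    Inh(%) = 100 (v_control - v_sample) / v_control, unclipped.
    """
    if control.v <= 0:
        raise DomainError("control rate must be positive")
    conc = np.array(sorted(per_concentration), dtype=float)
    inh = np.array(
        [100.0 * (control.v - per_concentration[c].v) / control.v for c in conc]
    )
    return DoseResponse(concentration_uM=conc, inhibition_pct=inh)


def _hill(conc, ic50, h, top):
    conc = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(conc > 0, (conc / ic50) ** h, 0.0)
    return top * ratio / (1.0 + ratio)


def fit_ic50(dr: DoseResponse) -> IC50Fit:
    """Hill fit of a dose-response curve; max inhibition capped at 100%.

    Requires >= 4 concentrations bracketing 50% inhibition.  When every
    point lies on one side of 50% the IC50 is not identifiable from the
    data and an indeterminate result is returned instead of an
    extrapolation.  If the nonlinear fit fails, a log-linear
    interpolation between the bracketing points is used and flagged.
    """
    conc, inh = dr.concentration_uM, dr.inhibition_pct
    pos = conc > 0
    conc, inh = conc[pos], inh[pos]
    if conc.size < 4:
        raise InputError(f"need >= 4 nonzero concentrations, got {conc.size}")
    if np.all(inh < 50.0) or np.all(inh > 50.0):
        return IC50Fit(
            ic50_uM=np.nan, hill_slope=np.nan,
            max_inhibition_pct=float(np.max(inh)),
            residual_sum_squares=np.nan, indeterminate=True,
            message="inhibition never crosses 50%; IC50 not identifiable",
        )
    order = np.argsort(conc)
    conc, inh = conc[order], inh[order]
    # crude bracket for the start value
    above = np.nonzero(inh >= 50.0)[0]
    ic50_guess = float(conc[above[0]])
    try:
        popt, _ = optimize.curve_fit(
            _hill, conc, inh,
            p0=[ic50_guess, 1.0, min(float(np.max(inh)) * 1.05, 100.0)],
            bounds=([1e-12, 0.05, 1.0], [np.inf, 20.0, 100.0]),
            maxfev=20000,
        )
        rss = float(np.sum((inh - _hill(conc, *popt)) ** 2))
        return IC50Fit(
            ic50_uM=float(popt[0]), hill_slope=float(popt[1]),
            max_inhibition_pct=float(popt[2]), residual_sum_squares=rss,
        )
    except RuntimeError:
        # log-linear interpolation between the two points bracketing 50%
        i = above[0]
        x0, x1 = np.log10(conc[i - 1]), np.log10(conc[i])
        y0, y1 = inh[i - 1], inh[i]
        xc = x0 + (50.0 - y0) * (x1 - x0) / (y1 - y0)
        return IC50Fit(
            ic50_uM=float(10**xc), hill_slope=np.nan,
            max_inhibition_pct=float(np.max(inh)),
            residual_sum_squares=np.nan, interpolated=True,
            message="Hill fit failed; IC50 interpolated between bracketing points",
        )


def lineweaver_burk(rates: dict[float, float]) -> MichaelisFit:
    """Unweighted OLS on double-reciprocal axes 1/v vs 1/[S].

    ``rates`` maps substrate concentration (mM) to rate v (uM/s).
    K_M = slope/intercept (mM), V_max = 1/intercept (uM/s).  A
    nonpositive intercept (1/V_max <= 0, i.e. the regression
    extrapolates to infinite or negative V_max) is flagged
    indeterminate; no negative constants are reported.
    """
    if len(rates) < 3:
        raise InputError(f"need >= 3 substrate concentrations, got {len(rates)}")
    s = np.array(sorted(rates), dtype=float)
    v = np.array([rates[c] for c in s], dtype=float)
    if np.any(s <= 0) or np.any(v <= 0):
        raise InputError("substrate concentrations and rates must all be positive")
    res = stats.linregress(1.0 / s, 1.0 / v)
    slope, intercept = float(res.slope), float(res.intercept)
    stderr = {"slope": float(res.stderr), "intercept": float(res.intercept_stderr)}
    if intercept <= 0:
        return MichaelisFit(
            K_M=np.nan, V_max=np.nan, intercept_1_over_vmax=intercept,
            slope_km_over_vmax=slope, stderr=stderr, indeterminate=True,
            message="nonpositive 1/V_max intercept; reciprocal fit indeterminate",
        )
    return MichaelisFit(
        K_M=slope / intercept, V_max=1.0 / intercept,
        intercept_1_over_vmax=intercept, slope_km_over_vmax=slope, stderr=stderr,
    )


def michaelis_menten_fit(rates: dict[float, float]) -> MichaelisFit:
    """Direct nonlinear Michaelis-Menten fit v = V_max S / (K_M + S).

    Cross-check for :func:`lineweaver_burk`; same units and container.
    """
    if len(rates) < 3:
        raise InputError(f"need >= 3 substrate concentrations, got {len(rates)}")
    s = np.array(sorted(rates), dtype=float)
    v = np.array([rates[c] for c in s], dtype=float)
    if np.any(s <= 0) or np.any(v <= 0):
        raise InputError("substrate concentrations and rates must all be positive")
    vmax0, km0 = float(np.max(v)) * 1.2, float(np.median(s))
    popt, _ = optimize.curve_fit(
        lambda ss, vmax, km: vmax * ss / (km + ss), s, v,
        p0=[vmax0, km0], bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=20000,
    )
    vmax, km = float(popt[0]), float(popt[1])
    return MichaelisFit(
        K_M=km, V_max=vmax, intercept_1_over_vmax=1.0 / vmax,
        slope_km_over_vmax=km / vmax,
    )


def classify_mechanism(
    free: MichaelisFit,
    inhibited: MichaelisFit,
    tolerance: float = DEFAULT_MECHANISM_TOLERANCE,
) -> MechanismCall:
    """Classify the inhibition mechanism from paired K_M / V_max fits.

    With r_K = K_M(inhibited)/K_M(free) and r_V = V_max(inh)/V_max(free):

    - noncompetitive: |r_K - 1| <= tol and r_V < 1 - tol
    - competitive:    |r_V - 1| <= tol and r_K > 1 + tol
    - uncompetitive:  r_K < 1 - tol, r_V < 1 - tol and r_K/r_V within tol of 1
    - mixed: anything else; indeterminate if either fit was flagged.
    """
    if not (0 < tolerance < 1):
        raise DomainError("tolerance must be a fraction in (0, 1)")
    if free.indeterminate or inhibited.indeterminate:
        return MechanismCall("indeterminate", np.nan, np.nan, tolerance)
    r_v = inhibited.V_max / free.V_max
    r_k = inhibited.K_M / free.K_M
    if abs(r_k - 1.0) <= tolerance and r_v < 1.0 - tolerance:
        label = "noncompetitive"
    elif abs(r_v - 1.0) <= tolerance and r_k > 1.0 + tolerance:
        label = "competitive"
    elif (
        r_k < 1.0 - tolerance
        and r_v < 1.0 - tolerance
        and abs(r_k / r_v - 1.0) <= tolerance
    ):
        label = "uncompetitive"
    else:
        label = "mixed"
    return MechanismCall(label, float(r_v), float(r_k), tolerance)
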