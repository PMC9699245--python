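"""Intrinsic-fluorescence quenching titrations: Stern-Volmer and binding.

A ligand titrated into a protein solution quenches the intrinsic (Trp)
fluorescence.  Two linearisations are used:

Stern-Volmer:   F0/F = 1 + K_sv [Q]   (slope K_sv; when the unquenched
fluorophore lifetime tau0 is known, the bimolecular quenching rate
constant is K_q = K_sv / tau0).

Double-log binding isotherm for a 1:1 (n-site) static association:

    log10[(F0 - F) / F] = log10 K_a + n log10 [Q]

giving the association constant K_a (M^-1) and the number of binding
sites n per protein molecule.  Concentrations are converted to molar
before taking logs so K_a comes out in M^-1.  Points with F >= F0
(no quenching; the log is undefined) are excluded and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError, InputError

__all__ = [
    "QuenchTitration",
    "SternVolmerFit",
    "BindingFit",
    "stern_volmer",
    "double_log_binding",
]


@dataclass(frozen=True)
class QuenchTitration:
    """Fluorescence titration series; the [Q] = 0 entry defines F0."""

    quencher_uM: np.ndarray  # strictly increasing from 0
    intensity: np.ndarray  # fluorescence at fixed emission wavelength, > 0
    condition: str = ""

    def __post_init__(self):
        q = np.asarray(self.quencher_uM, dtype=float)
        f = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "quencher_uM", q)
        object.__setattr__(self, "intensity", f)
        if q.ndim != 1 or f.shape != q.shape:
            raise InputError("quencher and intensity must be 1-D, equal length")
        if q.size < 2 or q[0] != 0:
            raise InputError("titration must start at quencher concentration 0")
        if not np.all(np.diff(q) > 0):
            raise InputError("quencher concentrations must be strictly increasing")
        if not np.all(f > 0):
            raise InputError("all intensities must be positive")

    @property
    def F0(self) -> float:
        return float(self.intensity[0])


@dataclass(frozen=True)
class SternVolmerFit:
    K_sv_per_uM: float
    K_sv_per_M: float
    K_q_per_M_s: float | None  # populated only when tau0 supplied
    tau0_s: float | None
    intercept: float  # expected near 1
    r_squared: float


@dataclass(frozen=True)
class BindingFit:
    K_a_per_M: float
    n_sites: float
    points_used: int
    excluded_points: int
    r_squared: float


def stern_volmer(tit: QuenchTitration, tau0: float | None = None) -> SternVolmerFit:
    """Least-squares of F0/F against [Q]; the slope is K_sv.

    All titration points (including [Q] = 0, where F0/F = 1 anchors the
    intercept) enter the regression.  tau0 in seconds, if given, adds
    K_q = K_sv / tau0 in M^-1 s^-1.
    """
    if np.count_nonzero(tit.quencher_uM > 0) < 3:
        raise InputError("need >= 3 nonzero quencher concentrations")
    if tau0 is not None and tau0 <= 0:
        raise DomainError("tau0 must be positive")
    y = tit.F0 / tit.intensity
    res = stats.linregress(tit.quencher_uM, y)
    ksv_uM = float(res.slope)
    ksv_M = ksv_uM * 1e6
    return SternVolmerFit(
        K_sv_per_uM=ksv_uM,
        K_sv_per_M=ksv_M,
        K_q_per_M_s=None if tau0 is None else ksv_M / tau0,
        tau0_s=tau0,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def double_log_binding(tit: QuenchTitration) -> BindingFit:
    """Double-logarithmic binding fit yielding K_a (M^-1) and n.

    Regresses log10[(F0-F)/F] on log10[Q in M] over the points with
    F < F0; the intercept is log10 K_a and the slope n.
    """
    q, f = tit.quencher_uM, tit.intensity
    nonzero = q > 0
    usable = nonzero & (f < tit.F0)
    excluded = int(np.count_nonzero(nonzero) - np.count_nonzero(usable))
    if np.count_nonzero(usable) < 3:
        raise InputError(
            f"need >= 3 quenched points (F < F0); "
            f"{excluded} of {int(np.count_nonzero(nonzero))} excluded"
        )
    x = np.log10(q[usable] * 1e-6)  # uM -> M
    y = np.log10((tit.F0 - f[usable]) / f[usable])
    res = stats.linregress(x, y)
    return BindingFit(
        K_a_per_M=float(10.0 ** res.intercept),
        n_sites=float(res.slope),
        points_used=int(np.count_nonzero(usable)),
        excluded_points=excluded,
        r_squared=float(res.rvalue**2),
    )
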