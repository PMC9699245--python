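"""DPPH radical-scavenging capacity (RSC) curves.

The stable radical DPPH absorbs strongly at 517 nm; an antioxidant
reduces it and bleaches the band.  RSC(%) at each antioxidant
concentration is 100 (A_control - A_sample) / A_control, where
A_control is the absorbance of DPPH alone.  Values are reported
unclipped — small negative values or values just above 100% are normal
measurement noise, not errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InputError

__all__ = ["DPPHSeries", "rsc_curve", "full_quench_concentration"]


@dataclass(frozen=True)
class DPPHSeries:
    """Absorbance-vs-concentration series from a DPPH assay."""

    concentration_uM: np.ndarray  # antioxidant, nonnegative increasing
    absorbance_517: np.ndarray  # AU
    control_absorbance: float  # DPPH alone, AU

    def __post_init__(self):
        c = np.asarray(self.concentration_uM, dtype=float)
        a = np.asarray(self.absorbance_517, dtype=float)
        object.__setattr__(self, "concentration_uM", c)
        object.__setattr__(self, "absorbance_517", a)
        if c.ndim != 1 or a.shape != c.shape or c.size == 0:
            raise InputError("concentration and absorbance must be 1-D, equal length")
        if np.any(c < 0) or not np.all(np.diff(c) > 0):
            raise InputError("concentrations must be nonnegative and increasing")
        if self.control_absorbance <= 0:
            raise DomainError("control absorbance must be positive")


def rsc_curve(series: DPPHSeries) -> list[tuple[float, float]]:
    """(concentration, RSC %) pairs, RSC = 100 (A_ctrl - A) / A_ctrl."""
    a0 = series.control_absorbance
    rsc = 100.0 * (a0 - series.absorbance_517) / a0
    return [(float(c), float(r)) for c, r in zip(series.concentration_uM, rsc)]


def full_quench_concentration(
    curve: list[tuple[float, float]], threshold: float = 99.0
) -> float | None:
    """Smallest measured concentration whose RSC reaches the threshold.

    Returns None when the threshold is never reached.  The default 99%
    treats readings within noise of complete bleaching as total quench.
    """
    if not curve:
        raise InputError("empty RSC curve")
    reached = sorted(c for c, r in curve if r >= threshold)
    return reached[0] if reached else None
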