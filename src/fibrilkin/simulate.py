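"""Seeded synthetic assay data with the structure the fitters assume.

Each generator samples a deterministic forward model plus Gaussian
noise from a ``numpy.random.default_rng`` seeded through
:class:`ScenarioConfig`, so identical (config, seed) always produces
identical data.  Ground-truth parameters are returned alongside the
data so tests can assert recovery.

Defaults emulate a 20 uM amyloid-beta(1-40) ThT aggregation experiment
(control nucleation rate k_n = 1.83e-5 s^-1, elongation
k_e = 175.73 M^-1 s^-1) with condition multipliers reproducing the
effect structure of flavonoid co-incubation (apigenin: k_n x3.2;
quercetin: k_n x4.5, k_e x0.46) and of enzyme-induced aggregation
(k_n x0.44, k_e x1.76); an Ellman assay with V_max = 3.94 uM/s and
K_M = 0.15 (substrate-axis units) under noncompetitive inhibition; a
1:1 static quench with K_a = 5.3e5 M^-1; and a steep DPPH bleaching
curve centred at 1.5 uM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aggregation import ThTTrace, autocatalytic_fraction
from .dpph import DPPHSeries
from .enzyme import DEFAULT_EPSILON, ProgressCurve
from .errors import DomainError
from .quenching import QuenchTitration

__all__ = [
    "ScenarioConfig",
    "AggregationScenario",
    "gen_tht",
    "gen_ellman",
    "gen_quench",
    "gen_dpph",
    "noncompetitive_rate",
    "competitive_rate",
    "uncompetitive_rate",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Sampling and noise settings shared by all generators.

    noise_fraction is the Gaussian noise sigma as a fraction of the
    relevant signal amplitude (traces) or of the rate (progress
    curves); sampling is (start, stop, step) in seconds for
    time-resolved assays.
    """

    seed: int = 0
    n_replicates: int = 3
    noise_fraction: float = 0.02
    sampling: tuple[float, float, float] = (0.0, 21600.0, 60.0)

    def __post_init__(self):
        if self.noise_fraction < 0:
            raise DomainError("noise_fraction must be >= 0")
        if self.n_replicates < 1:
            raise DomainError("need at least one replicate")
        start, stop, step = self.sampling
        if not (stop > start and step > 0):
            raise DomainError("sampling must satisfy stop > start, step > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def time_grid(self) -> np.ndarray:
        start, stop, step = self.sampling
        n = int(np.floor((stop - start) / step)) + 1
        return start + step * np.arange(n)


# (k_n factor, k_e factor) relative to the free-peptide control
DEFAULT_CONDITION_MULTIPLIERS: dict[str, tuple[float, float]] = {
    "control": (1.0, 1.0),
    "apigenin": (3.2, 1.0),
    "quercetin": (4.5, 0.46),
    "ache": (0.44, 1.76),
}


@dataclass(frozen=True)
class AggregationScenario:
    """Ground truth for ThT trace generation.

    The control condition has nucleation rate k_n = rho * k and
    elongation rate k_e = k / a; each entry of condition_multipliers
    scales (k_n, k_e) and the per-condition (k', rho') are recomputed
    as k' = k_e' a, rho' = k_n' / k'.
    """

    k: float = 175.73 * 20e-6  # s^-1  (= k_e * a of the control)
    rho: float = 1.83e-5 / (175.73 * 20e-6)  # = k_n / k
    monomer_concentration: float = 20e-6  # M
    baseline: float = 100.0  # fluorescence units
    amplitude: float = 900.0
    condition_multipliers: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_MULTIPLIERS)
    )

    def __post_init__(self):
        if self.k <= 0 or self.rho <= 0 or self.monomer_concentration <= 0:
            raise DomainError("k, rho and monomer concentration must be positive")
        if self.amplitude <= 0:
            raise DomainError("amplitude must be positive")
        for cond, (fn, fe) in self.condition_multipliers.items():
            if fn <= 0 or fe <= 0:
                raise DomainError(f"multipliers for {cond!r} must be positive")

    def condition_params(self, condition: str) -> tuple[float, float]:
        """(k', rho') for a condition after applying its multipliers."""
        fn, fe = self.condition_multipliers[condition]
        a = self.monomer_concentration
        k_n = self.rho * self.k * fn
        k_e = (self.k / a) * fe
        k_prime = k_e * a
        return k_prime, k_n / k_prime


def gen_tht(
    scenario: AggregationScenario | None = None,
    config: ScenarioConfig | None = None,
) -> tuple[list[ThTTrace], dict]:
    """Generate noisy ThT traces for every scenario condition.

    signal = baseline + amplitude * f(t; k', rho') + N(0, sigma) with
    sigma = noise_fraction * amplitude.  Returns the traces and a
    ground-truth dict keyed by condition.
    """
    scenario = scenario or AggregationScenario()
    config = config or ScenarioConfig()
    rng = config.rng()
    t = config.time_grid()
    traces: list[ThTTrace] = []
    truth: dict = {"seed": config.seed, "conditions": {}}
    for cond in scenario.condition_multipliers:
        k, rho = scenario.condition_params(cond)
        clean = scenario.baseline + scenario.amplitude * autocatalytic_fraction(
            t, k, rho
        )
        truth["conditions"][cond] = {
            "k": k,
            "rho": rho,
            "k_n": rho * k,
            "k_e": k / scenario.monomer_concentration,
            "baseline": scenario.baseline,
            "amplitude": scenario.amplitude,
        }
        for rep in range(config.n_replicates):
            noise = rng.normal(
                0.0, config.noise_fraction * scenario.amplitude, size=t.shape
            )
            traces.append(
                ThTTrace(
                    time=t,
                    signal=clean + noise,
                    condition=cond,
                    replicate=rep,
                    monomer_concentration=scenario.monomer_concentration,
                )
            )
    return traces, truth


def noncompetitive_rate(S, I, V_max, K_M, K_i):
    """v = V_max S / ((K_M + S)(1 + I/K_i)); at I = K_i the rate is
    exactly half the uninhibited one for any S."""
    return V_max * S / ((K_M + S) * (1.0 + I / K_i))


def competitive_rate(S, I, V_max, K_M, K_i):
    """v = V_max S / (K_M (1 + I/K_i) + S); V_max unchanged as S -> inf."""
    return V_max * S / (K_M * (1.0 + I / K_i) + S)


def uncompetitive_rate(S, I, V_max, K_M, K_i):
    """v = V_max S / (K_M + S (1 + I/K_i)); both apparent K_M and V_max
    scale down by 1/(1 + I/K_i)."""
    return V_max * S / (K_M + S * (1.0 + I / K_i))


_RATE_LAWS = {
    "noncompetitive": noncompetitive_rate,
    "competitive": competitive_rate,
    "uncompetitive": uncompetitive_rate,
}

# 1..4 uL of 15 mM substrate into ~200 uL give roughly these mM levels
DEFAULT_SUBSTRATE_GRID_MM = (0.075, 0.15, 0.225, 0.30)
DEFAULT_INHIBITOR_GRID_UM = (0.0, 10.0, 20.0, 40.0, 80.0, 160.0)


def gen_ellman(
    mechanism: str = "noncompetitive",
    K_M: float = 0.15,  # substrate-axis units (mM)
    V_max: float = 3.94,  # uM/s
    K_i: float = 40.0,  # uM
    substrate_grid=DEFAULT_SUBSTRATE_GRID_MM,
    inhibitor_grid=DEFAULT_INHIBITOR_GRID_UM,
    config: ScenarioConfig | None = None,
    duration_s: float = 120.0,
    dt_s: float = 5.0,
    baseline_AU: float = 0.05,
    epsilon: float = DEFAULT_EPSILON,
) -> tuple[list[ProgressCurve], dict]:
    """Linear early-phase Ellman progress curves under a chosen mechanism.

    The true rate v(S, I) follows the exact standard rate law for the
    mechanism; noise_fraction perturbs each replicate's rate
    multiplicatively (rate noise), and the absorbance trace is the
    corresponding exact line A(t) = A0 + v * epsilon * 1e-6 * t.
    """
    if mechanism not in _RATE_LAWS:
        raise DomainError(f"unknown mechanism {mechanism!r}")
    if min(K_M, V_max, K_i) <= 0:
        raise DomainError("kinetic constants must be positive")
    config = config or ScenarioConfig(sampling=(0.0, 120.0, 5.0))
    rng = config.rng()
    law = _RATE_LAWS[mechanism]
    t = np.arange(0.0, duration_s + 0.5 * dt_s, dt_s)
    curves: list[ProgressCurve] = []
    truth: dict = {
        "mechanism": mechanism,
        "K_M": K_M,
        "V_max": V_max,
        "K_i": K_i,
        "seed": config.seed,
        "rates": {},
    }
    for inhibitor in inhibitor_grid:
        for substrate in substrate_grid:
            v_true = float(law(substrate, inhibitor, V_max, K_M, K_i))
            truth["rates"][(float(substrate), float(inhibitor))] = v_true
            for rep in range(config.n_replicates):
                v = v_true * (1.0 + rng.normal(0.0, config.noise_fraction))
                slope_AU = v * epsilon * 1e-6  # uM/s -> AU/s at 1 cm path
                curves.append(
                    ProgressCurve(
                        time=t,
                        absorbance=baseline_AU + slope_AU * t,
                        substrate_mM=float(substrate),
                        inhibitor_uM=float(inhibitor),
                        condition=mechanism,
                        replicate=rep,
                    )
                )
    return curves, truth


# sequential 1..10 uL additions of 10 uM ligand into ~140 uL, in uM
DEFAULT_QUENCHER_GRID_UM = tuple(
    round(10.0 * v / (140.0 + v), 4) for v in range(1, 11)
)


def gen_quench(
    K_a: float = 5.3e5,  # M^-1
    n: float = 1.0,
    F0: float = 1000.0,
    quencher_grid_uM=DEFAULT_QUENCHER_GRID_UM,
    config: ScenarioConfig | None = None,
    condition: str = "ligand",
) -> tuple[QuenchTitration, dict]:
    """Titration from the n-site isotherm (F0-F)/F = (K_a [Q])^n.

    Multiplicative intensity noise (1 + N(0, noise_fraction)) is
    applied to every nonzero-[Q] point; the [Q]=0 point stays exactly
    F0 so that the reference intensity is noise-free.
    """
    if K_a <= 0 or F0 <= 0 or n <= 0:
        raise DomainError("K_a, n and F0 must be positive")
    config = config or ScenarioConfig()
    rng = config.rng()
    q = np.asarray(quencher_grid_uM, dtype=float)
    f = F0 / (1.0 + (K_a * q * 1e-6) ** n)
    f = f * (1.0 + rng.normal(0.0, config.noise_fraction, size=f.shape))
    tit = QuenchTitration(
        quencher_uM=np.concatenate(([0.0], q)),
        intensity=np.concatenate(([F0], f)),
        condition=condition,
    )
    return tit, {"K_a": K_a, "n": n, "F0": F0, "seed": config.seed}


def gen_dpph(
    EC50: float = 1.5,  # uM
    hill: float = 7.0,
    control_A: float = 0.80,  # AU
    grid_uM=(1.0, 2.0, 3.0, 4.0, 10.0, 100.0),
    config: ScenarioConfig | None = None,
) -> tuple[DPPHSeries, dict]:
    """DPPH bleaching series A = A_ctrl (1 - c^h/(EC50^h + c^h)) + noise.

    The steep default Hill coefficient reproduces the sharp
    near-stoichiometric transition seen for strong scavengers
    (negligible bleach one concentration step below EC50, essentially
    complete two steps above).
    """
    if EC50 <= 0 or hill <= 0 or control_A <= 0:
        raise DomainError("EC50, hill and control absorbance must be positive")
    config = config or ScenarioConfig()
    rng = config.rng()
    c = np.asarray(grid_uM, dtype=float)
    quench = c**hill / (EC50**hill + c**hill)
    a = control_A * (1.0 - quench)
    a = a + rng.normal(0.0, config.noise_fraction * control_A, size=a.shape)
    series = DPPHSeries(
        concentration_uM=c, absorbance_517=a, control_absorbance=control_A
    )
    return series, {
        "EC50": EC50,
        "hill": hill,
        "control_A": control_A,
        "seed": config.seed,
    }
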