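"""Initial rates, IC50, double-reciprocal fits and mechanism calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fibrilkin as fk
from fibrilkin.enzyme import DEFAULT_EPSILON
from fibrilkin.errors import DomainError, InputError
from fibrilkin.simulate import noncompetitive_rate


def linear_curve(slope, n=25, dt=5.0, a0=0.05, substrate=0.15, inhibitor=0.0):
    t = np.arange(n) * dt
    return fk.ProgressCurve(
        time=t, absorbance=a0 + slope * t, substrate_mM=substrate,
        inhibitor_uM=inhibitor,
    )


class TestInitialRate:
    def test_exact_linear_slope(self):
        est = fk.initial_rate(linear_curve(0.001))
        # 0.001 AU/s over 13,600 M^-1 cm^-1 and 1 cm -> uM/s
        assert est.v == pytest.approx(0.001 / 13600 * 1e6, rel=1e-9)
        assert est.v == pytest.approx(0.0735294, abs=1e-6)
        assert est.r_squared == pytest.approx(1.0)

    def test_constant_absorbance(self):
        est = fk.initial_rate(linear_curve(0.0))
        assert est.v == 0.0
        assert est.r_squared == 0.0

    def test_seeded_noisy_slope(self):
        rng = np.random.default_rng(11)
        t = np.arange(25) * 5.0
        curve = fk.ProgressCurve(
            time=t, absorbance=0.05 + 0.001 * t + rng.normal(0, 0.002, t.shape)
        )
        est = fk.initial_rate(curve)
        assert est.slope_AU == pytest.approx(0.001, rel=0.05)

    def test_window_outside_span(self):
        with pytest.raises(InputError):
            fk.initial_rate(linear_curve(0.001), window=1e6)

    def test_epsilon_scaling(self):
        v1 = fk.initial_rate(linear_curve(0.001)).v
        v2 = fk.initial_rate(linear_curve(0.001), epsilon=DEFAULT_EPSILON / 2).v
        assert v2 == pytest.approx(2 * v1)


class TestDoseResponse:
    @staticmethod
    def _rate(v):
        return fk.RateEstimate(v=v, slope_AU=np.nan, window=120, r_squared=1.0,
                               n_points=25)

    def test_values(self):
        dr = fk.dose_response(
            self._rate(2.0), {10.0: self._rate(1.0), 20.0: self._rate(2.0)}
        )
        assert dr.inhibition_pct[0] == pytest.approx(50.0)
        assert dr.inhibition_pct[1] == pytest.approx(0.0)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(DomainError):
            fk.dose_response(self._rate(0.0), {10.0: self._rate(1.0)})

    def test_noncompetitive_half_at_ki(self):
        # v = Vmax S / ((K_M + S)(1 + I/K_i)): I = K_i halves v for any S
        for S in (0.05, 0.15, 3.0):
            v0 = noncompetitive_rate(S, 0.0, 3.94, 0.15, 40.0)
            vi = noncompetitive_rate(S, 40.0, 3.94, 0.15, 40.0)
            dr = fk.dose_response(self._rate(v0), {40.0: self._rate(vi)})
            assert dr.inhibition_pct[0] == pytest.approx(50.0, rel=1e-12)


class TestIC50:
    def test_exact_hill_recovery(self):
        conc = np.array([5.0, 10.0, 20.0, 40.0, 80.0, 160.0])
        inh = 100.0 * conc / (40.0 + conc)  # h = 1, max = 100
        fit = fk.fit_ic50(fk.DoseResponse(conc, inh))
        assert not fit.indeterminate
        assert fit.ic50_uM == pytest.approx(40.0, rel=1e-6)
        assert fit.hill_slope == pytest.approx(1.0, rel=1e-6)
        assert fit.max_inhibition_pct == pytest.approx(100.0, rel=1e-6)

    def test_inhibition_at_ic50_is_half_max(self):
        conc = np.array([5.0, 10.0, 20.0, 40.0, 80.0, 160.0])
        inh = 90.0 * conc**1.3 / (30.0**1.3 + conc**1.3)
        fit = fk.fit_ic50(fk.DoseResponse(conc, inh))
        model_at_ic50 = fit.max_inhibition_pct * 0.5
        interp = 90.0 * fit.ic50_uM**1.3 / (30.0**1.3 + fit.ic50_uM**1.3)
        assert interp == pytest.approx(model_at_ic50, rel=1e-6)

    def test_one_sided_data_indeterminate(self):
        conc = np.array([1.0, 2.0, 4.0, 8.0])
        fit = fk.fit_ic50(fk.DoseResponse(conc, np.array([5.0, 9.0, 15.0, 24.0])))
        assert fit.indeterminate
        assert np.isnan(fit.ic50_uM)

    def test_noncompetitive_ic50_equals_ki(self):
        # closed-form property: IC50 of noncompetitive inhibition is K_i
        # independent of substrate concentration
        K_i = 40.0
        for S in (0.05, 0.3):
            v0 = noncompetitive_rate(S, 0.0, 3.94, 0.15, K_i)
            conc = np.array([5.0, 10.0, 20.0, 40.0, 80.0, 160.0])
            inh = 100.0 * (v0 - noncompetitive_rate(S, conc, 3.94, 0.15, K_i)) / v0
            fit = fk.fit_ic50(fk.DoseResponse(conc, inh))
            assert fit.ic50_uM == pytest.approx(K_i, rel=0.02)

    def test_too_few_concentrations(self):
        with pytest.raises(InputError):
            fk.fit_ic50(fk.DoseResponse(np.array([1.0, 10.0, 100.0]),
                                        np.array([10.0, 50.0, 90.0])))


def mm_rates(vmax, km, substrates):
    return {S: vmax * S / (km + S) for S in substrates}


class TestLineweaverBurk:
    def test_exact_recovery(self):
        fit = fk.lineweaver_burk(mm_rates(3.94, 0.15, (0.075, 0.15, 0.225, 0.30)))
        assert fit.V_max == pytest.approx(3.94, rel=1e-9)
        assert fit.K_M == pytest.approx(0.15, rel=1e-9)
        assert fit.slope_km_over_vmax == pytest.approx(0.15 / 3.94, rel=1e-9)
        assert fit.intercept_1_over_vmax == pytest.approx(1 / 3.94, rel=1e-9)

    def test_rate_halving_scales_vmax_only(self):
        rates = mm_rates(3.94, 0.15, (0.075, 0.15, 0.225, 0.30))
        halved = {s: v / 2 for s, v in rates.items()}
        f1, f2 = fk.lineweaver_burk(rates), fk.lineweaver_burk(halved)
        assert f2.V_max == pytest.approx(f1.V_max / 2, rel=1e-9)
        assert f2.K_M == pytest.approx(f1.K_M, rel=1e-9)

    def test_nonpositive_intercept_flagged(self):
        # rates increasing faster than Michaelis-Menten allows push the
        # reciprocal intercept below zero
        fit = fk.lineweaver_burk({0.1: 1.0, 0.2: 3.0, 0.4: 10.0})
        assert fit.indeterminate
        assert np.isnan(fit.V_max)

    def test_noisy_recovery_within_15pct(self):
        errs_km, errs_vmax = [], []
        rates = mm_rates(3.94, 0.15, (0.075, 0.15, 0.225, 0.30))
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = {s: v * (1 + rng.normal(0, 0.03)) for s, v in rates.items()}
            fit = fk.lineweaver_burk(noisy)
            errs_km.append(abs(fit.K_M / 0.15 - 1))
            errs_vmax.append(abs(fit.V_max / 3.94 - 1))
        assert np.median(errs_km) < 0.15
        assert np.median(errs_vmax) < 0.15

    def test_nonlinear_cross_check_agrees(self):
        rates = mm_rates(2.5, 0.4, (0.1, 0.2, 0.4, 0.8))
        lb = fk.lineweaver_burk(rates)
        nl = fk.michaelis_menten_fit(rates)
        assert nl.V_max == pytest.approx(lb.V_max, rel=1e-6)
        assert nl.K_M == pytest.approx(lb.K_M, rel=1e-6)

    def test_too_few_levels(self):
        with pytest.raises(InputError):
            fk.lineweaver_burk({0.1: 1.0, 0.2: 1.5})


def fit_from(vmax, km):
    return fk.MichaelisFit(
        K_M=km, V_max=vmax, intercept_1_over_vmax=1 / vmax,
        slope_km_over_vmax=km / vmax,
    )


class TestClassifyMechanism:
    def test_published_flavonoid_pairs_noncompetitive(self):
        free = fit_from(3.94, 0.15)
        for vmax_i, km_i in [(1.28, 0.15), (1.74, 0.20)]:
            call = fk.classify_mechanism(free, fit_from(vmax_i, km_i))
            assert call.label == "noncompetitive"

    def test_synthetic_competitive(self):
        call = fk.classify_mechanism(fit_from(3.94, 0.15), fit_from(3.94, 0.45))
        assert call.label == "competitive"

    def test_synthetic_uncompetitive(self):
        call = fk.classify_mechanism(fit_from(3.94, 0.15), fit_from(1.97, 0.075))
        assert call.label == "uncompetitive"

    def test_mixed_fallback(self):
        call = fk.classify_mechanism(fit_from(3.94, 0.15), fit_from(1.0, 0.6))
        assert call.label == "mixed"

    def test_indeterminate_propagates(self):
        bad = fk.MichaelisFit(
            K_M=np.nan, V_max=np.nan, intercept_1_over_vmax=-0.1,
            slope_km_over_vmax=0.1, indeterminate=True,
        )
        assert fk.classify_mechanism(fit_from(3.94, 0.15), bad).label == "indeterminate"

    def test_substrate_order_invariance(self):
        # the call is a pure function of the fitted ratios, so feeding
        # the same rates in any order yields the same label
        rates = mm_rates(3.94, 0.15, (0.075, 0.15, 0.225, 0.30))
        inhibited = {s: v / 3 for s, v in rates.items()}
        shuffled = dict(reversed(list(inhibited.items())))
        c1 = fk.classify_mechanism(fk.lineweaver_burk(rates),
                                   fk.lineweaver_burk(inhibited))
        c2 = fk.classify_mechanism(fk.lineweaver_burk(rates),
                                   fk.lineweaver_burk(shuffled))
        assert c1 == c2
        assert c1.label == "noncompetitive"

    @given(
        r_v=st.floats(0.05, 2.0), r_k=st.floats(0.05, 2.0),
        tol=st.floats(0.05, 0.6),
    )
    @settings(max_examples=100, deadline=None)
    def test_label_reproducible_from_ratios(self, r_v, r_k, tol):
        free = fit_from(1.0, 1.0)
        call = fk.classify_mechanism(free, fit_from(r_v, r_k), tolerance=tol)
        repeat = fk.classify_mechanism(
            fit_from(2.0, 3.0), fit_from(2.0 * r_v, 3.0 * r_k), tolerance=tol
        )
        assert call.label == repeat.label
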