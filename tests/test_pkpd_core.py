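"""Structural model: allometry, closed-form kinetics, effect site, score."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad, solve_ivp

from serinepkpd import (
    DoseEvent,
    PKParameters,
    Regimen,
    allometric_scale,
    baseline_with_age,
    effect_site_concentration,
    effect_site_from_regimen,
    equilibration_half_life,
    plasma_concentration,
    score_model,
    simulate_profile,
)


class TestAllometry:
    @pytest.mark.parametrize(
        "value, weight, exponent, ref, expected",
        [
            (100.0, 70.0, 0.75, 70.0, 100.0),  # identity at reference weight
            (100.0, 35.0, 1.0, 70.0, 50.0),  # linear exponent halves with weight
            (504.0, 20.5, 0.75, 70.0, 504.0 * (20.5 / 70.0) ** 0.75),
        ],
    )
    def test_power_law(self, value, weight, exponent, ref, expected):
        assert allometric_scale(value, weight, exponent, ref) == pytest.approx(expected)

    @given(
        value=st.floats(1.0, 1e4),
        weight=st.floats(5.0, 120.0),
        exponent=st.floats(0.0, 1.5),
    )
    @settings(max_examples=50, derandomize=True)
    def test_matches_log_space_computation(self, value, weight, exponent):
        direct = allometric_scale(value, weight, exponent, 70.0)
        log_space = np.exp(np.log(value) + exponent * (np.log(weight) - np.log(70.0)))
        assert direct == pytest.approx(log_space, rel=1e-12)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            allometric_scale(100.0, 0.0, 0.75, 70.0)
        with pytest.raises(ValueError):
            allometric_scale(100.0, 20.0, 0.75, -1.0)


class TestEquilibrationHalfLife:
    def test_published_ke0_gives_about_15_weeks(self):
        assert round(equilibration_half_life(0.0065)) == 15

    def test_one_week(self):
        assert equilibration_half_life(np.log(2) / 7.0) == pytest.approx(1.0)

    def test_upper_ci_rate(self):
        assert equilibration_half_life(0.010) == pytest.approx(9.9, abs=0.05)

    def test_requires_positive_rate(self):
        with pytest.raises(ValueError):
            equilibration_half_life(0.0)


class TestBaselineWithAge:
    def test_identity_at_reference_age(self):
        assert baseline_with_age(48.51, 5.0, -0.21) == pytest.approx(48.51)

    def test_null_exponent(self):
        assert baseline_with_age(37.0, 9.3, 0.0) == pytest.approx(37.0)

    def test_power_arithmetic(self):
        expected = 48.51 * 2.0 ** (-0.21)
        assert baseline_with_age(48.51, 10.0, -0.21) == pytest.approx(expected)


class TestScoreModel:
    def test_baseline(self):
        assert score_model(48.51, 0.015, 0.5, 0.0, 0.0) == pytest.approx(48.51)

    def test_progression_only(self):
        assert score_model(48.51, 0.015, 0.0022, 0.0, 84.0) == pytest.approx(49.77)

    def test_delta_with_drug(self):
        delta = score_model(48.51, 0.015, 0.0022, 500.0, 84.0) - 48.51
        assert delta == pytest.approx(0.015 * 84 + 0.0022 * 500)


@pytest.fixture(scope="module")
def pk(params):
    return params.pk.scaled_to(25.0)


@pytest.fixture(scope="module")
def single_dose(params):
    return Regimen([DoseEvent(0.0, 7000.0, params.pk.d1)])


def _ode_oracle(pk, regimen, ke0, t_eval):
    """Stiff ODE integration of depot-inflow/central/peripheral/effect-site."""
    start, rate, dur = regimen.arrays()
    k10, k12, k21 = pk.cl_f / pk.v1_f, pk.q_f / pk.v1_f, pk.q_f / pk.v2_f

    def rhs(t, y):
        inflow = np.sum(rate * ((t >= start) & (t < start + dur)))
        a1, a2, ce = y
        return [
            inflow - (k10 + k12) * a1 + k21 * a2,
            k12 * a1 - k21 * a2,
            ke0 * (a1 / pk.v1_f - ce),
        ]

    sol = solve_ivp(rhs, (0, t_eval.max()), [0.0, 0.0, 0.0], t_eval=t_eval,
                    method="LSODA", rtol=1e-11, atol=1e-9, max_step=0.02)
    return sol.y[0] / pk.v1_f, sol.y[2]


class TestPlasma:
    def test_empty_regimen_is_zero(self, pk):
        assert np.all(plasma_concentration(pk, Regimen(), [0.0, 1.0, 30.0]) == 0.0)

    def test_negative_time_rejected(self, pk, single_dose):
        with pytest.raises(ValueError):
            plasma_concentration(pk, single_dose, [-0.1])

    @pytest.mark.parametrize("draw", range(5))
    def test_matches_ode_oracle(self, draw):
        rng = np.random.default_rng(100 + draw)
        pk = PKParameters(
            cl_f=float(rng.uniform(200, 20000)),
            v1_f=float(rng.uniform(50, 3000)),
            q_f=float(rng.uniform(100, 8000)),
            v2_f=float(rng.uniform(100, 6000)),
            d1=float(rng.uniform(0.03, 0.2)),
        )
        ke0 = float(rng.uniform(0.004, 0.4))
        regimen = Regimen(Regimen.bid(float(rng.uniform(1, 10)), 0.0, 6.0, pk.d1))
        t = np.linspace(0.25, 12.0, 40)
        cp = plasma_concentration(pk, regimen, t)
        ce = effect_site_from_regimen(ke0, pk, regimen, t)
        cp_ode, ce_ode = _ode_oracle(pk, regimen, ke0, t)
        assert np.allclose(cp, cp_ode, rtol=1e-6, atol=1e-8 * cp.max())
        assert np.allclose(ce, ce_ode, rtol=1e-6, atol=1e-8 * max(ce.max(), 1e-12))

    def test_auc_equals_dose_over_clearance(self, pk, single_dose):
        auc, _ = quad(
            lambda t: plasma_concentration(pk, single_dose, [t])[0],
            0.0, 300.0, limit=400,
        )
        expected = 7000.0 * 1e3 / pk.cl_f  # ug*day/L
        assert auc == pytest.approx(expected, rel=1e-3)

    def test_superposition(self, pk, params):
        t = np.linspace(0.0, 10.0, 80)
        multi = Regimen(Regimen.bid(2.0, 0.0, 3.0, params.pk.d1))
        total = plasma_concentration(pk, multi, t)
        summed = np.zeros_like(t)
        for e in multi:
            single = Regimen([e])
            summed += plasma_concentration(pk, single, t)
        assert np.allclose(total, summed, rtol=1e-9)

    def test_dose_linearity(self, pk, params):
        t = np.linspace(0.0, 20.0, 60)
        reg = Regimen(Regimen.bid(3.0, 0.0, 7.0, params.pk.d1))
        cp1 = plasma_concentration(pk, reg, t)
        ce1 = effect_site_from_regimen(0.0065, pk, reg, t)
        cp2 = plasma_concentration(pk, reg.scaled(2.0), t)
        ce2 = effect_site_from_regimen(0.0065, pk, reg.scaled(2.0), t)
        assert np.allclose(cp2, 2 * cp1, rtol=1e-10)
        assert np.allclose(ce2, 2 * ce1, rtol=1e-10)

    def test_washout_to_zero(self, pk, single_dose):
        late = plasma_concentration(pk, single_dose, [400.0])[0]
        assert late < 1e-8


class TestEffectSite:
    def test_zero_plasma_gives_zero(self):
        ce = effect_site_concentration(0.0065, lambda t: np.zeros_like(t), [0, 10, 50])
        assert np.all(ce == 0.0)

    def test_constant_plasma_exponential_rise(self):
        ke0 = 0.0065
        t_half = np.log(2) / ke0  # ~106.6 days
        ce = effect_site_concentration(ke0, lambda t: np.full_like(t, 100.0), [t_half])
        assert ce[0] == pytest.approx(50.0, rel=1e-4)

    def test_requires_positive_ke0(self, pk, single_dose):
        with pytest.raises(ValueError):
            effect_site_from_regimen(0.0, pk, single_dose, [1.0])
        with pytest.raises(ValueError):
            effect_site_concentration(-1.0, lambda t: t, [1.0])

    def test_analytic_matches_generic_integrator(self, pk, params):
        reg = Regimen(Regimen.bid(4.0, 0.0, 10.0, params.pk.d1))
        t = np.linspace(0.0, 40.0, 30)
        exact = effect_site_from_regimen(0.0065, pk, reg, t)
        generic = effect_site_concentration(
            0.0065, lambda tt: plasma_concentration(pk, reg, tt), t, grid_step=0.01
        )
        assert np.allclose(exact, generic, rtol=2e-3, atol=1e-3 * exact.max())

    def test_effect_site_lags_plasma(self, pk, params):
        t = np.linspace(0.0, 60.0, 600)
        reg = Regimen(Regimen.bid(5.0, 0.0, 14.0, params.pk.d1))
        prof = simulate_profile(pk, 0.0065, reg, t)
        assert prof.effect_site.max() <= prof.plasma.max()
        assert t[np.argmax(prof.effect_site)] >= t[np.argmax(prof.plasma)]

    def test_effect_site_zero_before_dosing(self, pk, params):
        reg = Regimen(Regimen.bid(5.0, 10.0, 20.0, params.pk.d1))
        assert effect_site_from_regimen(0.0065, pk, reg, [0.0, 5.0, 9.9]).max() == 0.0
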