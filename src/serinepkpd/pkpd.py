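"""Deterministic structural PK-PD model.

Plasma kinetics follow a two-compartment disposition with zero-order
absorption and linear elimination; the solution is the closed-form
bi-exponential response to each zero-order input, superposed over dose
events.  The delayed clinical response is captured by a hypothetical
effect compartment

    dCe/dt = ke0 * (Cp(t) - Ce(t)),    Ce(0) = 0,

whose concentration drives the score linearly on top of a linear natural
progression:

    score(t) = E0_i + Kprog_i * t + Deff_i * Ce(t).

With ke0 = 0.0065 / day the effect site equilibrates with a half-life of
about 15 weeks, i.e. most of the clinical response builds up over the
whole 12-week treatment period.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .params import PKParameters
from .regimen import Regimen

__all__ = [
    "allometric_scale",
    "equilibration_half_life",
    "baseline_with_age",
    "score_model",
    "plasma_concentration",
    "effect_site_from_regimen",
    "effect_site_concentration",
    "ConcentrationProfile",
    "simulate_profile",
    "disposition",
]

DAYS_PER_WEEK = 7.0


def allometric_scale(
    value_ref: float, weight: float, exponent: float, ref_weight: float
) -> float:
    """Power-law body-weight scaling: value_ref * (weight/ref_weight)**exponent."""
    if not weight > 0:
        raise ValueError("weight must be positive")
    if not ref_weight > 0:
        raise ValueError("ref_weight must be positive")
    return value_ref * (weight / ref_weight) ** exponent


def equilibration_half_life(ke0: float) -> float:
    """Effect-site equilibration half-life in weeks, ln(2)/ke0."""
    if not ke0 > 0:
        raise ValueError("ke0 must be positive")
    return np.log(2.0) / ke0 / DAYS_PER_WEEK


def baseline_with_age(
    e0: float, age: float, beta_age: float, age_ref: float = 5.0
) -> float:
    """Typical baseline score at ``age``: e0 * (age/age_ref)**beta_age."""
    if not age > 0:
        raise ValueError("age must be positive")
    return e0 * (age / age_ref) ** beta_age


def score_model(e0_i, kprog_i, deff_i, ce, t):
    """Predicted score: baseline + natural progression + linear drug effect."""
    return e0_i + kprog_i * np.asarray(t) + deff_i * np.asarray(ce)


def disposition(pk: PKParameters) -> tuple[float, float, float, float]:
    """Macro constants (lam1, lam2, A1, A2) of the two-compartment model.

    The unit-bolus central concentration is A1*exp(-lam1 t) + A2*exp(-lam2 t)
    with lam1 > lam2 > 0.
    """
    k10 = pk.cl_f / pk.v1_f
    k12 = pk.q_f / pk.v1_f
    k21 = pk.q_f / pk.v2_f
    s = k10 + k12 + k21
    disc = np.sqrt(s * s - 4.0 * k10 * k21)
    lam1 = 0.5 * (s + disc)
    lam2 = 0.5 * (s - disc)
    a1 = (lam1 - k21) / (pk.v1_f * (lam1 - lam2))
    a2 = (k21 - lam2) / (pk.v1_f * (lam1 - lam2))
    return lam1, lam2, a1, a2


def _check_times(times) -> np.ndarray:
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    return t


def _plasma_terms(tau, dur, rate, lam, coef):
    """Per-(event, time) plasma contribution of one exponential mode.

    tau is time since event start; contributions are zero for tau <= 0.
    """
    a = rate * coef / lam
    tau_c = np.clip(tau, 0.0, dur)  # elapsed infusion time
    u = np.maximum(tau - dur, 0.0)  # time since end of infusion
    val = a * (-np.expm1(-lam * tau_c)) * np.exp(-lam * u)
    return np.where(tau > 0, val, 0.0)


def plasma_concentration(pk: PKParameters, regimen: Regimen, times) -> np.ndarray:
    """Plasma concentration (ug/L) at ``times`` for an individual's regimen.

    ``pk`` must already be scaled to the individual (see
    :meth:`PKParameters.scaled_to`).  Superposition over dose events of
    the closed-form two-compartment response to zero-order inputs.
    """
    t = _check_times(times)
    if len(regimen) == 0:
        return np.zeros_like(t)
    lam1, lam2, a1, a2 = disposition(pk)
    start, rate, dur = regimen.arrays()
    tau = t[None, :] - start[:, None]  # (events, times)
    cp = _plasma_terms(tau, dur[:, None], rate[:, None], lam1, a1)
    cp += _plasma_terms(tau, dur[:, None], rate[:, None], lam2, a2)
    return cp.sum(axis=0)


def _safe_ke0(ke0, lam):
    """Nudge ke0 away from an exact disposition eigenvalue (removable pole)."""
    ke0 = np.asarray(ke0, dtype=float)
    close = np.abs(ke0 - lam) < 1e-9 * np.maximum(lam, 1.0)
    return np.where(close, ke0 * (1.0 + 1e-7) + 1e-300, ke0)


def _ce_event_mode(tau, dur, rate, lam, coef, ke0):
    """Effect-site contribution of one exponential mode of one event.

    Exact convolution of the zero-order/bi-exponential plasma piece with
    the first-order effect-compartment kernel.
    """
    ke0 = _safe_ke0(ke0, lam)
    a = rate * coef / lam
    w = ke0 / (ke0 - lam)
    tau_c = np.clip(tau, 0.0, dur)
    u = np.maximum(tau - dur, 0.0)
    e_lam_tc = np.exp(-lam * tau_c)
    e_ke0_tc = np.exp(-ke0 * tau_c)
    # during (or at end of) the infusion window
    ce_end = a * (-np.expm1(-ke0 * tau_c) - w * (e_lam_tc - e_ke0_tc))
    # free relaxation after the infusion: carry Ce(end) with the ke0 kernel
    # plus the response to the decaying plasma tail
    b = a * (-np.expm1(-lam * np.minimum(tau_c, dur)))
    e_ke0_u = np.exp(-ke0 * u)
    tail = b * w * (np.exp(-lam * u) - e_ke0_u)
    val = ce_end * e_ke0_u + tail
    return np.where(tau > 0, val, 0.0)


def effect_site_from_regimen(
    ke0: float, pk: PKParameters, regimen: Regimen, times
) -> np.ndarray:
    """Effect-site concentration (ug/L) by exact piecewise-analytic convolution."""
    if not ke0 > 0:
        raise ValueError("ke0 must be positive")
    t = _check_times(times)
    if len(regimen) == 0:
        return np.zeros_like(t)
    lam1, lam2, a1, a2 = disposition(pk)
    start, rate, dur = regimen.arrays()
    tau = t[None, :] - start[:, None]
    ce = _ce_event_mode(tau, dur[:, None], rate[:, None], lam1, a1, ke0)
    ce += _ce_event_mode(tau, dur[:, None], rate[:, None], lam2, a2, ke0)
    return ce.sum(axis=0)


def effect_site_concentration(
    ke0: float,
    plasma: Callable[[np.ndarray], np.ndarray] | tuple[Sequence, Sequence],
    times,
    grid_step: float = 0.25,
) -> np.ndarray:
    """Effect-site concentration for an arbitrary plasma profile.

    ``plasma`` is either a callable Cp(t) or a ``(t, cp)`` sample pair
    (linearly interpolated).  Integrates dCe/dt = ke0 (Cp - Ce), Ce(0)=0,
    with an exact exponential update on a grid of step <= ``grid_step``
    days assuming Cp piecewise linear between grid nodes.
    """
    if not ke0 > 0:
        raise ValueError("ke0 must be positive")
    t_out = _check_times(times)
    t_end = float(t_out.max(initial=0.0))
    grid = np.union1d(np.arange(0.0, t_end + grid_step, grid_step), t_out)
    if callable(plasma):
        cp = np.asarray(plasma(grid), dtype=float)
    else:
        ts, cs = plasma
        cp = np.interp(grid, np.asarray(ts, float), np.asarray(cs, float))
    ce = np.zeros_like(grid)
    h = np.diff(grid)
    ek = np.exp(-ke0 * h)
    # Cp linear on [t_k, t_k+h]: Ce_{k+1} = Ce_k e^{-ke0 h} + a(1-e^{-ke0 h})
    #   + b (h - (1-e^{-ke0 h})/ke0),  a = Cp_k, b = slope
    slope = np.diff(cp) / np.where(h > 0, h, 1.0)
    for k in range(len(h)):
        one_m = -np.expm1(-ke0 * h[k])
        ce[k + 1] = ce[k] * ek[k] + cp[k] * one_m + slope[k] * (h[k] - one_m / ke0)
    return np.interp(t_out, grid, ce)


@dataclass(frozen=True)
class ConcentrationProfile:
    """Time course of plasma and effect-site concentration."""

    times: np.ndarray  # days
    plasma: np.ndarray  # ug/L
    effect_site: np.ndarray  # ug/L

    def __post_init__(self) -> None:
        if np.any(self.plasma < -1e-9) or np.any(self.effect_site < -1e-9):
            raise ValueError("concentrations must be nonnegative")


def simulate_profile(
    pk: PKParameters, ke0: float, regimen: Regimen, times
) -> ConcentrationProfile:
    t = _check_times(times)
    return ConcentrationProfile(
        times=t,
        plasma=plasma_concentration(pk, regimen, t),
        effect_site=effect_site_from_regimen(ke0, pk, regimen, t),
    )
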