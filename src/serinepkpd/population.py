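"""Inter-individual variability layer.

Random effects (etas) live on a Gaussian scale: log-scale for ke0, E0 and
Deff (log-normal parameters), linear scale for Kprog.  The E0 and Kprog
etas share a correlation; all others are independent.  Canonical eta
column order throughout the package: (ke0, e0, deff, kprog).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import PDParameters, PKParameters, RandomEffectSpec
from .pkpd import baseline_with_age

__all__ = ["IndividualParameters", "sample_etas", "individualize", "add_residual"]

ETA_NAMES = ("ke0", "e0", "deff", "kprog")


@dataclass(frozen=True)
class IndividualParameters:
    """One subject's realised PD and weight-scaled PK parameters."""

    ke0_i: float
    e0_i: float
    deff_i: float
    kprog_i: float
    cl_i: float
    v1_i: float
    q_i: float
    v2_i: float


def sample_etas(
    spec: RandomEffectSpec, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` correlated eta vectors, shape (n, 4).

    Columns follow :data:`ETA_NAMES`.  (eta_e0, eta_kprog) are jointly
    normal with correlation ``spec.corr_e0_kprog``; eta_ke0 and eta_deff
    are independent.  Deterministic given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cov = spec.omega_matrix()  # raises on invalid configuration
    rng = np.random.default_rng(seed)
    # Draw via a Cholesky-like factor tolerant of zero variances.
    sd = np.sqrt(np.diag(cov))
    z = rng.standard_normal((n, 4))
    etas = z * sd
    if spec.corr_e0_kprog != 0.0 and sd[1] > 0 and sd[3] > 0:
        rho = spec.corr_e0_kprog
        etas[:, 3] = sd[3] * (rho * z[:, 1] + np.sqrt(1.0 - rho**2) * z[:, 3])
    return etas


def individualize(
    pk: PKParameters,
    pd_params: PDParameters,
    etas: np.ndarray,
    age: float,
    weight: float,
) -> IndividualParameters:
    """Combine fixed effects, covariates and one eta vector into an individual.

    ke0, E0 (after its age power function) and Deff are scaled by exp(eta);
    Kprog is shifted additively.  PK is allometrically scaled by weight and
    carries no eta (the PK model is fixed from a prior analysis).
    """
    etas = np.asarray(etas, dtype=float)
    if etas.shape != (4,):
        raise ValueError("etas must be a length-4 vector (ke0, e0, deff, kprog)")
    pk_i = pk.scaled_to(weight)
    e0_typ = baseline_with_age(pd_params.e0, age, pd_params.beta_age, pd_params.age_ref)
    return IndividualParameters(
        ke0_i=pd_params.ke0 * np.exp(etas[0]),
        e0_i=e0_typ * np.exp(etas[1]),
        deff_i=pd_params.deff * np.exp(etas[2]),
        kprog_i=pd_params.kprog + etas[3],
        cl_i=pk_i.cl_f,
        v1_i=pk_i.v1_f,
        q_i=pk_i.q_f,
        v2_i=pk_i.v2_f,
    )


def add_residual(
    predicted, sigma_add: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Observed = predicted + N(0, sigma_add^2), elementwise."""
    if sigma_add < 0:
        raise ValueError("sigma_add must be >= 0")
    predicted = np.asarray(predicted, dtype=float)
    rng = np.random.default_rng(seed)
    return predicted + rng.standard_normal(predicted.shape) * sigma_add
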