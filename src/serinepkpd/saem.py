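"""Stochastic approximation EM for the nonlinear mixed-effects score model.

The E-step samples subject etas from their conditional posterior with a
bank of Metropolis-Hastings kernels (prior-independence, joint random
walk, componentwise random walk), vectorised across subjects.  Because
the transformed individual parameters are Gaussian around a linear
predictor X_i theta, the M-step is closed form: generalised least squares
for the fixed effects and empirical moments (projected onto the modelled
diagonal-plus-one-correlation structure) for the eta covariance.  During
the exploratory phase variance updates are annealed downward slowly so
the chains keep exploring before the smoothing phase averages them out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import PredictionEngine
from .laplace import laplace_ofv

__all__ = ["SaemOptions", "SaemState", "run_saem"]


@dataclass
class SaemOptions:
    n_burn: int = 300
    n_smooth: int = 100
    n_chains: int = 2
    n_sweeps: int = 2  # MH kernel sweeps per iteration
    anneal: float = 0.95  # variance decrease cap per burn-in iteration
    target_accept: float = 0.3
    corr_bound: float = 0.98


@dataclass
class SaemState:
    theta: np.ndarray  # (p,)
    omega4: np.ndarray  # (4, 4)
    sigma2: float
    trace: dict = field(default_factory=dict)


def _project_omega(cov: np.ndarray, bound: float) -> tuple[np.ndarray, float]:
    """Project a full 4x4 moment matrix onto the modelled structure."""
    var = np.maximum(np.diag(cov), 1e-12)
    sd = np.sqrt(var)
    rho = float(np.clip(cov[1, 3] / (sd[1] * sd[3]), -bound, bound))
    out = np.diag(var)
    out[1, 3] = out[3, 1] = rho * sd[1] * sd[3]
    return out, rho


def _gls_theta(X: np.ndarray, om_inv: np.ndarray, psi_bar: np.ndarray) -> np.ndarray:
    a = np.einsum("nap,ab,nbq->pq", X, om_inv, X)
    b = np.einsum("nap,ab,nb->p", X, om_inv, psi_bar)
    return np.linalg.solve(a, b)


def run_saem(
    engine: PredictionEngine,
    X: np.ndarray,
    theta0: np.ndarray,
    omega0: np.ndarray,
    sigma0: float,
    seed: int,
    options: SaemOptions | None = None,
) -> SaemState:
    """Run SAEM and return the final parameter state with iteration traces.

    ``X`` (n, 4, p) is the per-subject design mapping fixed effects to the
    transformed parameter means.  All four etas must carry positive
    variance in ``omega0`` (parameters without IIV are fit by the direct
    or Laplace route instead).
    """
    opt = options or SaemOptions()
    rng = np.random.default_rng(seed)
    n = engine.n_subjects
    p = X.shape[2]
    if np.any(np.diag(omega0) <= 0):
        raise ValueError("SAEM requires positive variance for every eta")

    theta = theta0.astype(float).copy()
    omega = omega0.astype(float).copy()
    sigma2 = float(sigma0) ** 2
    total_obs = engine.n_obs

    # start every chain at the conditional eta modes of the initial
    # parameters: the first iterations then sample near the posterior
    # instead of inflating sigma against unadapted etas
    mu0 = np.einsum("nap,p->na", X, theta)
    mode = laplace_ofv(engine, mu0, omega, sigma2, max_iter=25).eta_hat
    etas = [mode.copy() for _ in range(opt.n_chains)]

    def data_m2ll(eta):
        psi = np.einsum("nap,p->na", X, theta) + eta
        f, _ = engine.predict(psi)
        r = engine.y - f
        return engine.rss_by_subject(r) / sigma2, r

    # adaptive proposal scales
    scale_joint = 0.4
    scale_comp = np.full(4, 0.4)

    s_psi = np.zeros((n, 4))
    s_pp = np.zeros((n, 4, 4))
    s_rss = 0.0
    n_iter = opt.n_burn + opt.n_smooth
    trace = {"theta": np.empty((n_iter, p)), "omega": np.empty((n_iter, 4)),
             "rho": np.empty(n_iter), "sigma": np.empty(n_iter)}

    for it in range(n_iter):
        burn = it < opt.n_burn
        gamma = 1.0 if burn else 1.0 / (it - opt.n_burn + 1)
        om_inv = np.linalg.inv(omega)
        chol = np.linalg.cholesky(omega)
        sd = np.sqrt(np.diag(omega))

        psi_mean = np.zeros((n, 4))
        pp_mean = np.zeros((n, 4, 4))
        rss_mean = 0.0
        mu = np.einsum("nap,p->na", X, theta)
        for c in range(opt.n_chains):
            eta = etas[c]
            d2, _ = data_m2ll(eta)
            prior_q = np.einsum("ni,ij,nj->n", eta, om_inv, eta)

            for _ in range(opt.n_sweeps):
                # kernel 1: independence proposal from the eta prior
                prop = rng.standard_normal((n, 4)) @ chol.T
                d2p, _ = data_m2ll(prop)
                acc = np.log(rng.uniform(size=n)) < 0.5 * (d2 - d2p)
                eta = np.where(acc[:, None], prop, eta)
                d2 = np.where(acc, d2p, d2)
                prior_q = np.where(
                    acc, np.einsum("ni,ij,nj->n", prop, om_inv, prop), prior_q
                )

                # kernel 2: joint random walk
                prop = eta + scale_joint * (rng.standard_normal((n, 4)) @ chol.T)
                d2p, _ = data_m2ll(prop)
                qp = np.einsum("ni,ij,nj->n", prop, om_inv, prop)
                acc = np.log(rng.uniform(size=n)) < 0.5 * (d2 + prior_q - d2p - qp)
                eta = np.where(acc[:, None], prop, eta)
                d2 = np.where(acc, d2p, d2)
                prior_q = np.where(acc, qp, prior_q)
                if burn:
                    scale_joint *= np.exp(0.05 * (acc.mean() - opt.target_accept))

                # kernel 3: componentwise random walk
                for j in range(4):
                    prop = eta.copy()
                    prop[:, j] += scale_comp[j] * sd[j] * rng.standard_normal(n)
                    d2p, _ = data_m2ll(prop)
                    qp = np.einsum("ni,ij,nj->n", prop, om_inv, prop)
                    acc = np.log(rng.uniform(size=n)) < 0.5 * (d2 + prior_q - d2p - qp)
                    eta = np.where(acc[:, None], prop, eta)
                    d2 = np.where(acc, d2p, d2)
                    prior_q = np.where(acc, qp, prior_q)
                    if burn:
                        scale_comp[j] *= np.exp(0.05 * (acc.mean() - opt.target_accept))

            etas[c] = eta
            psi = mu + eta
            psi_mean += psi / opt.n_chains
            pp_mean += psi[:, :, None] * psi[:, None, :] / opt.n_chains
            _, r = data_m2ll(eta)
            rss_mean += float(r @ r) / opt.n_chains

        # stochastic approximation of the sufficient statistics
        s_psi += gamma * (psi_mean - s_psi)
        s_pp += gamma * (pp_mean - s_pp)
        s_rss += gamma * (rss_mean - s_rss)

        # M-step: GLS fixed effects, moment-matched structured covariance
        theta = _gls_theta(X, np.linalg.inv(omega), s_psi)
        mu = np.einsum("nap,p->na", X, theta)
        cov = (
            s_pp
            - s_psi[:, :, None] * mu[:, None, :]
            - mu[:, :, None] * s_psi[:, None, :]
            + mu[:, :, None] * mu[:, None, :]
        ).mean(axis=0)
        new_omega, rho = _project_omega(cov, opt.corr_bound)
        new_sigma2 = s_rss / total_obs
        if burn:
            # temper variance moves: a single-draw moment estimate is noisy,
            # and letting sigma/omega jump up re-heats the chains
            lo = np.diag(omega) * opt.anneal
            hi = np.diag(omega) / opt.anneal
            var = np.clip(np.diag(new_omega), lo, hi)
            sdv = np.sqrt(var)
            new_omega = np.diag(var)
            new_omega[1, 3] = new_omega[3, 1] = rho * sdv[1] * sdv[3]
            new_sigma2 = float(np.clip(new_sigma2, sigma2 * opt.anneal, sigma2 / opt.anneal))
        omega = new_omega
        sigma2 = new_sigma2

        trace["theta"][it] = theta
        trace["omega"][it] = np.sqrt(np.diag(omega))
        trace["rho"][it] = rho
        trace["sigma"][it] = np.sqrt(sigma2)

    return SaemState(theta=theta, omega4=omega, sigma2=sigma2, trace=trace)
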