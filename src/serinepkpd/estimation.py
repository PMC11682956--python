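"""Nonlinear mixed-effects estimation of the score model.

The PK side is always held fixed (population PK parameters come from a
prior analysis; only weight enters through allometry).  Estimated are
the PD fixed effects (ke0, E0, covariate exponents, Deff, Kprog), the
eta SDs with the E0-Kprog correlation, and the additive residual SD.

Two routes are exposed: SAEM (stochastic, the primary estimator) and
Laplace (deterministic; also provides the OFV used for likelihood-ratio
tests and the numerical information matrix behind standard errors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .engine import PredictionEngine
from .laplace import laplace_ofv
from .params import ModelParameters, PDParameters, PKParameters, RandomEffectSpec, default_parameters
from .saem import SaemOptions, run_saem
from .trial import TrialDataset

__all__ = [
    "CovariateEffect",
    "FitResult",
    "BootstrapResult",
    "LrtDecision",
    "fit",
    "neg2_loglik",
    "lrt_decision",
    "covariate_search",
    "bootstrap",
    "moment_init",
    "DEFAULT_COVARIATES",
]

_PARAM_ROW = {"ke0": 0, "e0": 1, "deff": 2, "kprog": 3}
_BASE_NAMES = ("log_ke0", "log_e0", "log_deff", "kprog")


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate-parameter relation.

    Continuous covariates enter as power functions normalised to
    ``reference`` (log-ratio column on the transformed scale); ``sex``
    enters as a female indicator.  On log-normal parameters this is the
    usual power model; on the linear-scale Kprog it is an additive shift
    per log weight-ratio.
    """

    param: str  # ke0 | e0 | deff | kprog
    covariate: str  # age | weight | sex | baseline_serine
    reference: float | None = None  # None -> dataset median

    @property
    def name(self) -> str:
        return f"beta_{self.param}_{self.covariate}"


DEFAULT_COVARIATES: tuple[CovariateEffect, ...] = (
    CovariateEffect("e0", "age", reference=5.0),
)


def _covariate_column(demog: pd.DataFrame, eff: CovariateEffect) -> np.ndarray:
    if eff.covariate == "sex":
        return (demog["sex"].to_numpy() == "female").astype(float)
    vals = demog[eff.covariate].to_numpy(float)
    ref = eff.reference if eff.reference is not None else float(np.median(vals))
    if not ref > 0 or np.any(vals <= 0):
        raise ValueError(f"covariate {eff.covariate} must be positive for a power model")
    return np.log(vals / ref)


def build_design(
    demog: pd.DataFrame, covariates: Sequence[CovariateEffect]
) -> tuple[np.ndarray, list[str]]:
    """Design tensor X (n, 4, p) mapping fixed effects to transformed means."""
    n = len(demog)
    p = 4 + len(covariates)
    X = np.zeros((n, 4, p))
    for j in range(4):
        X[:, j, j] = 1.0
    names = list(_BASE_NAMES)
    for k, eff in enumerate(covariates):
        X[:, _PARAM_ROW[eff.param], 4 + k] = _covariate_column(demog, eff)
        names.append(eff.name)
    return X, names


def _theta_init(params: ModelParameters, covariates: Sequence[CovariateEffect]) -> np.ndarray:
    theta = [
        math.log(params.pd.ke0),
        math.log(params.pd.e0),
        math.log(params.pd.deff),
        params.pd.kprog,
    ]
    for eff in covariates:
        if eff.param == "e0" and eff.covariate == "age":
            theta.append(params.pd.beta_age)
        else:
            theta.append(0.0)
    return np.array(theta)


@dataclass
class FitResult:
    """Estimation output: estimates, uncertainty, OFV and bookkeeping."""

    estimates: dict  # fixed effects on the natural scale
    omegas: dict  # eta SDs
    corr_e0_kprog: float
    sigma_add: float
    ofv: float | None
    converged: bool
    method: str
    seed: int | None
    n_subjects: int
    n_obs: int
    se: dict | None = None
    rse_percent: dict | None = None
    covariates: tuple = ()
    trace: dict | None = field(default=None, repr=False)

    def to_model_parameters(self, pk: PKParameters) -> ModelParameters:
        est = self.estimates
        return ModelParameters(
            pk=pk,
            pd=PDParameters(
                ke0=est["ke0"],
                e0=est["e0"],
                beta_age=est.get("beta_age", est.get("beta_e0_age", 0.0)),
                deff=est["deff"],
                kprog=est["kprog"],
            ),
            ranef=RandomEffectSpec(
                omega_ke0=self.omegas["omega_ke0"],
                omega_e0=self.omegas["omega_e0"],
                omega_deff=self.omegas["omega_deff"],
                omega_kprog=self.omegas["omega_kprog"],
                corr_e0_kprog=self.corr_e0_kprog,
                sigma_add=self.sigma_add,
            ),
        )

    def to_dict(self) -> dict:
        return {
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "omegas": {k: float(v) for k, v in self.omegas.items()},
            "corr_e0_kprog": float(self.corr_e0_kprog),
            "sigma_add": float(self.sigma_add),
            "ofv": None if self.ofv is None else float(self.ofv),
            "converged": bool(self.converged),
            "method": self.method,
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
            "se": None if self.se is None else {k: float(v) for k, v in self.se.items()},
            "rse_percent": None
            if self.rse_percent is None
            else {k: float(v) for k, v in self.rse_percent.items()},
            "covariates": [(e.param, e.covariate) for e in self.covariates],
        }


def moment_init(dataset: TrialDataset, pk: PKParameters | None = None) -> ModelParameters:
    """Method-of-moments starting values from baseline scores and the
    placebo slope; drug/effect-site parameters start at documented
    defaults (ke0 0.01/day, Deff 0.001 L/ug) since raw scores carry
    little direct information about them."""
    pk = pk or default_parameters().pk
    obs = dataset.observations
    obs = obs[~obs["missing"]]
    demog = dataset.demographics.set_index("id")
    base = obs[obs["time"] == 0.0].set_index("id")["score"]
    ages = demog.loc[base.index, "age"].to_numpy(float)
    ly = np.log(np.maximum(base.to_numpy(float), 1.0))
    la = np.log(ages / 5.0)
    slope, intercept = np.polyfit(la, ly, 1)
    resid = ly - (intercept + slope * la)
    kprog0 = 0.01
    placebo_ids = demog.index[demog["arm"] == "placebo"] if "arm" in demog else []
    slopes = []
    for sid in placebo_ids:
        sub = obs[obs["id"] == sid].set_index("time")["score"]
        if 0.0 in sub.index and 84.0 in sub.index:
            slopes.append((sub[84.0] - sub[0.0]) / 84.0)
    if slopes:
        kprog0 = float(np.mean(slopes))
    return ModelParameters(
        pk=pk,
        pd=PDParameters(
            ke0=0.01,
            e0=float(np.exp(intercept)),
            beta_age=float(slope),
            deff=0.001,
            kprog=kprog0,
        ),
        ranef=RandomEffectSpec(
            omega_ke0=0.3,
            omega_e0=float(np.clip(np.std(resid), 0.05, 1.0)),
            omega_deff=1.0,
            omega_kprog=0.02,
            corr_e0_kprog=0.0,
            sigma_add=2.0,
        ),
    )


def _omega4_from_spec(spec: RandomEffectSpec) -> np.ndarray:
    return spec.omega_matrix()


def _result_from_state(
    theta, names, omega4, sigma2, *, method, seed, engine, covariates, ofv, converged, trace=None
) -> FitResult:
    sd = np.sqrt(np.diag(omega4))
    rho = float(omega4[1, 3] / (sd[1] * sd[3])) if sd[1] > 0 and sd[3] > 0 else 0.0
    estimates = {
        "ke0": float(np.exp(theta[0])),
        "e0": float(np.exp(theta[1])),
        "deff": float(np.exp(theta[2])),
        "kprog": float(theta[3]),
    }
    for k, name in enumerate(names[4:]):
        estimates[name] = float(theta[4 + k])
    for eff, name in zip(covariates, names[4:]):
        if eff.param == "e0" and eff.covariate == "age":
            estimates["beta_age"] = estimates[name]
    omegas = {
        "omega_ke0": float(sd[0]),
        "omega_e0": float(sd[1]),
        "omega_deff": float(sd[2]),
        "omega_kprog": float(sd[3]),
    }
    return FitResult(
        estimates=estimates,
        omegas=omegas,
        corr_e0_kprog=rho,
        sigma_add=float(np.sqrt(sigma2)),
        ofv=ofv,
        converged=converged,
        method=method,
        seed=seed,
        n_subjects=engine.n_subjects,
        n_obs=engine.n_obs,
        covariates=tuple(covariates),
        trace=trace,
    )


# ---------------------------------------------------------------------------
# transformed outer parameter vector for the Laplace route / SE computation


def _pack(theta, omega4, sigma2, est_var):
    sd = np.sqrt(np.diag(omega4))
    z = list(theta)
    for j in np.flatnonzero(est_var):
        z.append(math.log(sd[j]))
    if est_var[1] and est_var[3]:
        rho = omega4[1, 3] / (sd[1] * sd[3])
        z.append(np.arctanh(np.clip(rho, -0.99, 0.99)))
    z.append(0.5 * math.log(sigma2))
    return np.array(z)


def _unpack(z, p, est_var):
    theta = np.array(z[:p])
    sd = np.zeros(4)
    k = p
    for j in np.flatnonzero(est_var):
        sd[j] = math.exp(z[k])
        k += 1
    omega4 = np.diag(sd**2)
    if est_var[1] and est_var[3]:
        rho = math.tanh(z[k])
        omega4[1, 3] = omega4[3, 1] = rho * sd[1] * sd[3]
        k += 1
    sigma2 = math.exp(2 * z[k])
    return theta, omega4, sigma2


def _make_ofv(engine, X, est_var, warm):
    def ofv_of_z(z):
        theta, omega4, sigma2 = _unpack(z, X.shape[2], est_var)
        mu = np.einsum("nap,p->na", X, theta)
        res = laplace_ofv(engine, mu, omega4, sigma2, eta0=warm.get("eta"))
        warm["eta"] = res.eta_hat
        return res.ofv

    return ofv_of_z


def _fit_direct(engine, X, theta0):
    """No-eta model: maximum likelihood = nonlinear least squares, with the
    residual variance profiled out analytically."""

    def resid(theta):
        mu = np.einsum("nap,p->na", X, theta)
        f, _ = engine.predict(mu)
        return engine.y - f

    sol = optimize.least_squares(resid, theta0, method="lm", xtol=1e-14, ftol=1e-14)
    rss = float(sol.fun @ sol.fun)
    sigma2 = max(rss / engine.n_obs, 1e-12)
    ofv = rss / sigma2 + engine.n_obs * math.log(2 * math.pi * sigma2)
    return sol.x, sigma2, ofv, sol.success


def fit(
    dataset: TrialDataset,
    init: ModelParameters | None = None,
    pk: PKParameters | None = None,
    method: str = "saem",
    covariates: Sequence[CovariateEffect] = DEFAULT_COVARIATES,
    seed: int = 0,
    saem_options: SaemOptions | None = None,
    polish: bool = True,
    compute_ofv: bool = True,
    compute_se: bool = False,
) -> FitResult:
    """Fit the PD mixed-effects model with the PK held fixed.

    ``init`` supplies starting values (method-of-moments defaults when
    omitted).  Etas whose omega is zero in ``init`` are treated as
    structurally absent; if any of the four core etas is absent the SAEM
    route is unavailable and the deterministic route is used instead.
    Reproducible given ``seed``.
    """
    init = init or moment_init(dataset, pk)
    pk = pk or init.pk
    engine = PredictionEngine(dataset, pk)
    X, names = build_design(dataset.demographics.reset_index(drop=True), covariates)
    theta0 = _theta_init(init, covariates)
    omega0 = _omega4_from_spec(init.ranef)
    sigma0 = init.ranef.sigma_add if init.ranef.sigma_add > 0 else 1.0
    est_var = np.diag(omega0) > 0

    used_method = method
    if method == "saem" and not est_var.all():
        used_method = "laplace"

    trace = None
    if used_method == "saem":
        state = run_saem(
            engine, X, theta0, omega0, sigma0, seed=seed, options=saem_options
        )
        theta, omega4, sigma2 = state.theta, state.omega4, state.sigma2
        trace = state.trace
        converged = bool(np.all(np.isfinite(theta)))
        if polish and converged:
            # deterministic refinement: descend the Laplace OFV from the
            # SAEM end point to remove residual stochastic drift
            warm: dict = {}
            fun = _make_ofv(engine, X, est_var, warm)
            z0 = _pack(theta, omega4, sigma2, est_var)
            sol = optimize.minimize(
                fun, z0, method="L-BFGS-B",
                options={"maxiter": 60, "eps": 1e-4, "ftol": 1e-12, "gtol": 1e-6},
            )
            if np.isfinite(sol.fun) and sol.fun <= fun(z0) + 1e-9:
                theta, omega4, sigma2 = _unpack(sol.x, X.shape[2], est_var)
                used_method = "saem+polish"
    elif used_method == "laplace":
        if not est_var.any():
            theta, sigma2, _, ok = _fit_direct(engine, X, theta0)
            omega4 = np.zeros((4, 4))
            converged = ok
        else:
            warm: dict = {}
            fun = _make_ofv(engine, X, est_var, warm)
            z0 = _pack(theta0, omega0, sigma0**2, est_var)
            sol = optimize.minimize(
                fun, z0, method="L-BFGS-B",
                options={"maxiter": 200, "eps": 1e-4, "ftol": 1e-10},
            )
            theta, omega4, sigma2 = _unpack(sol.x, X.shape[2], est_var)
            converged = bool(sol.success or sol.fun < fun(z0))
    else:
        raise ValueError(f"unknown estimation method {method!r}")

    ofv = None
    if compute_ofv:
        mu = np.einsum("nap,p->na", X, theta)
        ofv = laplace_ofv(engine, mu, omega4, sigma2).ofv

    result = _result_from_state(
        theta, names, omega4, sigma2,
        method=used_method, seed=seed, engine=engine, covariates=covariates,
        ofv=ofv, converged=converged, trace=trace,
    )
    if compute_se:
        _attach_se(result, engine, X, theta, omega4, sigma2, est_var, names)
    return result


def _attach_se(result, engine, X, theta, omega4, sigma2, est_var, names):
    """Standard errors from the numerical Fisher information of the Laplace
    OFV on the transformed scale, delta-method back-transformed; RSE% is
    100*SE/|estimate|."""
    warm: dict = {}
    fun = _make_ofv(engine, X, est_var, warm)
    z = _pack(theta, omega4, sigma2, est_var)
    m = len(z)
    h = 1e-3
    hess = np.zeros((m, m))
    f0 = fun(z)
    fp = np.zeros(m)
    fm = np.zeros(m)
    for i in range(m):
        zp, zm = z.copy(), z.copy()
        zp[i] += h
        zm[i] -= h
        fp[i] = fun(zp)
        fm[i] = fun(zm)
        hess[i, i] = (fp[i] - 2 * f0 + fm[i]) / h**2
    for i in range(m):
        for j in range(i + 1, m):
            zpp, zpm, zmp, zmm = z.copy(), z.copy(), z.copy(), z.copy()
            zpp[[i, j]] += h
            zmm[[i, j]] -= h
            zpm[i] += h
            zpm[j] -= h
            zmp[i] -= h
            zmp[j] += h
            hess[i, j] = hess[j, i] = (fun(zpp) - fun(zpm) - fun(zmp) + fun(zmm)) / (4 * h**2)
    try:
        cov = 2.0 * np.linalg.inv(hess)
        se_z = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        return
    # delta method back to the natural scale
    se: dict[str, float] = {}
    p = X.shape[2]
    natural = [
        ("ke0", result.estimates["ke0"]),
        ("e0", result.estimates["e0"]),
        ("deff", result.estimates["deff"]),
        ("kprog", 1.0),
    ]
    for i, (name, scale) in enumerate(natural):
        se[name] = se_z[i] * (scale if name != "kprog" else 1.0)
    for k, name in enumerate(names[4:]):
        se[name] = se_z[4 + k]
    idx = p
    for j in np.flatnonzero(est_var):
        oname = f"omega_{('ke0', 'e0', 'deff', 'kprog')[j]}"
        se[oname] = se_z[idx] * result.omegas[oname]
        idx += 1
    if est_var[1] and est_var[3]:
        se["corr_e0_kprog"] = se_z[idx] * (1 - result.corr_e0_kprog**2)
        idx += 1
    se["sigma_add"] = se_z[idx] * result.sigma_add
    result.se = se
    values = {**result.estimates, **result.omegas,
              "corr_e0_kprog": result.corr_e0_kprog, "sigma_add": result.sigma_add}
    result.rse_percent = {
        k: 100.0 * v / abs(values[k]) for k, v in se.items() if values.get(k)
    }


def neg2_loglik(
    params: ModelParameters,
    dataset: TrialDataset,
    covariates: Sequence[CovariateEffect] = DEFAULT_COVARIATES,
) -> float:
    """Laplace -2 log marginal likelihood of ``dataset`` under ``params``."""
    engine = PredictionEngine(dataset, params.pk)
    X, _ = build_design(dataset.demographics.reset_index(drop=True), covariates)
    theta = _theta_init(params, covariates)
    omega4 = _omega4_from_spec(params.ranef)
    if not params.ranef.sigma_add > 0:
        raise ValueError("sigma_add must be positive to evaluate the likelihood")
    mu = np.einsum("nap,p->na", X, theta)
    return laplace_ofv(engine, mu, omega4, params.ranef.sigma_add**2).ofv


@dataclass(frozen=True)
class LrtDecision:
    accept_full: bool
    p_value: float
    delta_ofv: float
    critical: float


def lrt_decision(
    ofv_full: float,
    ofv_reduced: float,
    df: int = 1,
    alpha: float = 0.05,
    tolerance: float = 0.5,
) -> LrtDecision:
    """Chi-square likelihood-ratio test on an OFV drop (df >= 1).

    ``tolerance`` absorbs optimizer noise: a reduced-model OFV slightly
    below the full model's is clamped to zero; a larger violation means
    the models are not nested (or a fit failed) and raises.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    delta = ofv_reduced - ofv_full
    if delta < -tolerance:
        raise ValueError("ofv_reduced must not be below ofv_full (nested models)")
    delta = max(delta, 0.0)
    critical = float(stats.chi2.ppf(1 - alpha, df))
    p = float(stats.chi2.sf(delta, df))
    return LrtDecision(accept_full=delta > critical, p_value=p, delta_ofv=delta, critical=critical)


@dataclass
class CovariateSearchResult:
    selected: tuple[CovariateEffect, ...]
    log: list
    final_fit: FitResult


def covariate_search(
    dataset: TrialDataset,
    candidates: Sequence[CovariateEffect] | None = None,
    forward_alpha: float = 0.05,
    backward_alpha: float = 0.01,
    init: ModelParameters | None = None,
    pk: PKParameters | None = None,
    seed: int = 0,
    **fit_kwargs,
) -> CovariateSearchResult:
    """Stepwise forward-selection / backward-elimination covariate search.

    Each candidate is tested by a likelihood-ratio test (df=1) between the
    current model and the model with the candidate added (forward) or
    removed (backward).
    """
    if candidates is None:
        candidates = [
            CovariateEffect(p, c)
            for p in ("e0", "kprog", "deff")
            for c in ("age", "weight", "sex", "baseline_serine")
            if c == "sex" or c in dataset.demographics.columns
        ]
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    fit_kwargs.setdefault("compute_ofv", True)

    def fit_with(covs):
        return fit(dataset, init=init, pk=pk, covariates=tuple(covs), seed=seed, **fit_kwargs)

    selected: list[CovariateEffect] = []
    log: list[dict] = []
    current = fit_with(selected)
    remaining = list(candidates)
    while remaining:
        trials = []
        for cand in remaining:
            res = fit_with(selected + [cand])
            dec = lrt_decision(res.ofv, current.ofv, df=1, alpha=forward_alpha)
            log.append({"step": "forward", "candidate": cand.name,
                        "delta_ofv": dec.delta_ofv, "p": dec.p_value,
                        "accepted": dec.accept_full})
            trials.append((cand, res, dec))
        sig = [t for t in trials if t[2].accept_full]
        if not sig:
            break
        cand, res, _ = max(sig, key=lambda t: t[2].delta_ofv)
        selected.append(cand)
        remaining.remove(cand)
        current = res
    # backward elimination at the stricter level
    changed = True
    while changed and selected:
        changed = False
        for cand in list(selected):
            reduced = fit_with([c for c in selected if c is not cand])
            dec = lrt_decision(current.ofv, reduced.ofv, df=1, alpha=backward_alpha)
            log.append({"step": "backward", "candidate": cand.name,
                        "delta_ofv": dec.delta_ofv, "p": dec.p_value,
                        "kept": dec.accept_full})
            if not dec.accept_full:
                selected.remove(cand)
                current = reduced
                changed = True
                break
    return CovariateSearchResult(tuple(selected), log, current)


@dataclass
class BootstrapResult:
    replicates: pd.DataFrame
    median: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    n_converged: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"median": self.median, "ci2.5": self.ci_low, "ci97.5": self.ci_high}
        )


def _resample(dataset: TrialDataset, rng: np.random.Generator) -> TrialDataset:
    demog = dataset.demographics.reset_index(drop=True)
    n = len(demog)
    pick = rng.integers(0, n, size=n)
    ids = demog["id"].to_numpy()
    new_demog, new_doses, new_obs = [], [], []
    for new_id, j in enumerate(pick, start=1):
        old = ids[j]
        d = demog.iloc[[j]].copy()
        d["id"] = new_id
        new_demog.append(d)
        dd = dataset.doses[dataset.doses["id"] == old].copy()
        dd["id"] = new_id
        new_doses.append(dd)
        oo = dataset.observations[dataset.observations["id"] == old].copy()
        oo["id"] = new_id
        new_obs.append(oo)
    return TrialDataset(
        demographics=pd.concat(new_demog, ignore_index=True),
        doses=pd.concat(new_doses, ignore_index=True),
        observations=pd.concat(new_obs, ignore_index=True),
    )


def bootstrap(
    dataset: TrialDataset,
    n_runs: int = 200,
    seed: int = 0,
    identity_first: bool = False,
    **fit_kwargs,
) -> BootstrapResult:
    """Case bootstrap: resample subjects with replacement and refit.

    ``identity_first`` replaces the first replicate's resample with the
    identity (each subject once), a reproducibility check.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    n_conv = 0
    for k in range(n_runs):
        if identity_first and k == 0:
            ds = dataset
        else:
            ds = _resample(dataset, rng)
        res = fit(ds, seed=int(rng.integers(0, 2**31 - 1)), **fit_kwargs)
        row = {**res.estimates, **res.omegas,
               "corr_e0_kprog": res.corr_e0_kprog, "sigma_add": res.sigma_add}
        rows.append(row)
        n_conv += int(res.converged)
    reps = pd.DataFrame(rows)
    return BootstrapResult(
        replicates=reps,
        median=reps.median(),
        ci_low=reps.quantile(0.025),
        ci_high=reps.quantile(0.975),
        n_converged=n_conv,
    )
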