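"""Model evaluation: goodness-of-fit tables and prediction-corrected VPCs.

Everything is computed as numbers first (tables that tests can assert
on); plotting is a thin layer over the tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import PredictionEngine
from .estimation import DEFAULT_COVARIATES, build_design, _theta_init
from .laplace import laplace_ofv
from .params import ModelParameters
from .population import sample_etas
from .trial import TrialDataset

__all__ = ["gof_table", "pc_vpc", "VpcSummary", "plot_gof", "plot_vpc"]


def _setup(dataset, params, covariates):
    engine = PredictionEngine(dataset, params.pk)
    X, _ = build_design(dataset.demographics.reset_index(drop=True), covariates)
    theta = _theta_init(params, covariates)
    mu = np.einsum("nap,p->na", X, theta)
    return engine, mu


def gof_table(
    dataset: TrialDataset,
    params: ModelParameters,
    covariates=DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Observation-level goodness-of-fit records.

    PRED uses zero etas (population typical given covariates), IPRED the
    empirical-Bayes eta modes, and IWRES = (obs - IPRED) / sigma_add
    (NaN with sigma_add = 0, when weighted residuals are undefined).
    """
    engine, mu = _setup(dataset, params, covariates)
    pred, _ = engine.predict(mu)
    sigma = params.ranef.sigma_add
    omega4 = params.ranef.omega_matrix()
    if sigma > 0 and np.any(np.diag(omega4) > 0):
        modes = laplace_ofv(engine, mu, omega4, sigma**2).eta_hat
    else:
        modes = np.zeros((engine.n_subjects, 4))
    ipred, _ = engine.predict(mu + modes)
    iwres = (engine.y - ipred) / sigma if sigma > 0 else np.full_like(ipred, np.nan)
    ids = dataset.demographics.reset_index(drop=True)["id"].to_numpy()
    return pd.DataFrame(
        {
            "id": ids[engine.obs_subject],
            "time": engine.obs_time,
            "observed": engine.y,
            "pred": pred,
            "ipred": ipred,
            "iwres": iwres,
        }
    )


@dataclass
class VpcSummary:
    """Per-bin percentiles of prediction-corrected observations with
    simulation-based confidence envelopes."""

    table: pd.DataFrame
    n_sim: int
    percentiles: tuple = (5.0, 50.0, 95.0)


def pc_vpc(
    dataset: TrialDataset,
    params: ModelParameters,
    n_sim: int = 500,
    bins=None,
    seed: int = 0,
    covariates=DEFAULT_COVARIATES,
    percentiles=(5.0, 50.0, 95.0),
) -> VpcSummary:
    """Prediction-corrected visual predictive check.

    Observations and ``n_sim`` model-simulated replicates (same subjects,
    regimens and schedule) are corrected multiplicatively by the bin
    median population prediction, then summarised as percentiles; the
    envelopes are the 2.5/97.5% quantiles of each percentile across
    replicates.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    engine, mu = _setup(dataset, params, covariates)
    pred, _ = engine.predict(mu)
    if bins is None:
        bins = np.unique(engine.obs_time)
    bins = np.asarray(bins, dtype=float)
    # each observation joins the nearest bin
    bin_idx = np.argmin(np.abs(engine.obs_time[:, None] - bins[None, :]), axis=1)

    factor = np.ones_like(pred)
    for b in range(len(bins)):
        m = bin_idx == b
        if m.any():
            factor[m] = np.median(pred[m]) / pred[m]
    pc_obs = engine.y * factor

    rng = np.random.default_rng(seed)
    omega4 = params.ranef.omega_matrix()
    sigma = params.ranef.sigma_add
    sim_pcts = np.full((n_sim, len(bins), len(percentiles)), np.nan)
    for s in range(n_sim):
        etas = sample_etas(params.ranef, engine.n_subjects, rng)
        f, _ = engine.predict(mu + etas)
        y_sim = f + rng.standard_normal(engine.n_obs) * sigma
        pc_sim = y_sim * factor
        for b in range(len(bins)):
            m = bin_idx == b
            if m.any():
                sim_pcts[s, b] = np.percentile(pc_sim[m], percentiles)
    rows = []
    for b, t in enumerate(bins):
        m = bin_idx == b
        if not m.any():
            continue
        row = {"bin_time": t, "n_obs": int(m.sum())}
        obs_p = np.percentile(pc_obs[m], percentiles)
        for k, p in enumerate(percentiles):
            row[f"obs_p{p:g}"] = obs_p[k]
            row[f"sim_p{p:g}_lo"] = np.percentile(sim_pcts[:, b, k], 2.5)
            row[f"sim_p{p:g}_med"] = np.percentile(sim_pcts[:, b, k], 50)
            row[f"sim_p{p:g}_hi"] = np.percentile(sim_pcts[:, b, k], 97.5)
        rows.append(row)
    return VpcSummary(table=pd.DataFrame(rows), n_sim=n_sim, percentiles=tuple(percentiles))


def plot_gof(gof: pd.DataFrame, path) -> None:
    """Static 2x2 goodness-of-fit panel (obs vs PRED/IPRED, IWRES)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    lim = [gof[["observed", "pred", "ipred"]].min().min() - 2,
           gof[["observed", "pred", "ipred"]].max().max() + 2]
    for ax, col in zip(axes[0], ("pred", "ipred")):
        ax.plot(gof[col], gof["observed"], "o", ms=3, alpha=0.5)
        ax.plot(lim, lim, "k--", lw=1)
        ax.set_xlabel(col.upper())
        ax.set_ylabel("observed score")
    axes[1, 0].plot(gof["time"], gof["iwres"], "o", ms=3, alpha=0.5)
    axes[1, 0].axhline(0, color="k", ls="--", lw=1)
    axes[1, 0].set_xlabel("time (days)")
    axes[1, 0].set_ylabel("IWRES")
    axes[1, 1].plot(gof["ipred"], gof["iwres"], "o", ms=3, alpha=0.5)
    axes[1, 1].axhline(0, color="k", ls="--", lw=1)
    axes[1, 1].set_xlabel("IPRED")
    axes[1, 1].set_ylabel("IWRES")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_vpc(summary: VpcSummary, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = summary.table
    fig, ax = plt.subplots(figsize=(8, 5))
    colors = {5.0: "tab:blue", 50.0: "tab:red", 95.0: "tab:blue"}
    for p in summary.percentiles:
        c = colors.get(p, "tab:gray")
        ax.fill_between(tab["bin_time"], tab[f"sim_p{p:g}_lo"], tab[f"sim_p{p:g}_hi"],
                        alpha=0.25, color=c)
        ax.plot(tab["bin_time"], tab[f"obs_p{p:g}"], "o-", color=c,
                label=f"observed p{p:g}")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("prediction-corrected score")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
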