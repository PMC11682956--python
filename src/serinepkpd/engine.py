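"""Batched model evaluation over a whole trial dataset.

Estimation needs the predicted score at every observation for many
candidate eta vectors.  Plasma kinetics carry no eta (the PK model is
fixed given body weight), so everything except the ke0-dependent effect
site is precomputed per (dose event, observation) pair; evaluating the
model for new etas then costs a handful of vectorised exponentials.
"""

from __future__ import annotations

import numpy as np

from .params import PKParameters
from .pkpd import disposition
from .trial import TrialDataset

__all__ = ["PredictionEngine"]


class PredictionEngine:
    """Precomputed arrays mapping (subject etas) -> predicted scores.

    Subjects are indexed 0..n-1 in the order of ``dataset.demographics``.
    Observations (non-missing only) are flattened; ``obs_subject`` maps
    each observation to its subject index.
    """

    def __init__(self, dataset: TrialDataset, pk: PKParameters):
        demog = dataset.demographics.reset_index(drop=True)
        self.n_subjects = len(demog)
        self.ages = demog["age"].to_numpy(float)
        self.weights = demog["weight"].to_numpy(float)
        id_to_idx = {sid: i for i, sid in enumerate(demog["id"])}

        obs = dataset.observations
        obs = obs[~obs["missing"]]
        self.obs_subject = obs["id"].map(id_to_idx).to_numpy(int)
        self.obs_time = obs["time"].to_numpy(float)
        self.y = obs["score"].to_numpy(float)
        self.n_obs = len(self.y)

        # weight-scaled disposition constants per subject
        lam1 = np.empty(self.n_subjects)
        lam2 = np.empty(self.n_subjects)
        a1 = np.empty(self.n_subjects)
        a2 = np.empty(self.n_subjects)
        for i in range(self.n_subjects):
            lam1[i], lam2[i], a1[i], a2[i] = disposition(pk.scaled_to(self.weights[i]))

        # (event, observation) pairs with tau = t_obs - t_start > 0
        subj_of_obs: list[np.ndarray] = [
            np.flatnonzero(self.obs_subject == i) for i in range(self.n_subjects)
        ]
        p_obs, p_tau, p_dur, p_rate, p_subj = [], [], [], [], []
        doses = dataset.doses
        for sid, grp in doses.groupby("id"):
            i = id_to_idx[sid]
            oidx = subj_of_obs[i]
            if len(oidx) == 0 or len(grp) == 0:
                continue
            start = grp["time"].to_numpy(float)
            rate = grp["amount_mg"].to_numpy(float) * 1e3 / grp["duration"].to_numpy(float)
            dur = grp["duration"].to_numpy(float)
            tau = self.obs_time[oidx][None, :] - start[:, None]  # (E_i, M_i)
            keep = tau > 0
            e_idx, o_idx = np.nonzero(keep)
            p_obs.append(oidx[o_idx])
            p_tau.append(tau[keep])
            p_dur.append(dur[e_idx])
            p_rate.append(rate[e_idx])
            p_subj.append(np.full(keep.sum(), i))
        if p_obs:
            self.p_obs = np.concatenate(p_obs)
            tau = np.concatenate(p_tau)
            dur = np.concatenate(p_dur)
            rate = np.concatenate(p_rate)
            subj = np.concatenate(p_subj)
        else:
            self.p_obs = np.empty(0, int)
            tau = dur = rate = np.empty(0)
            subj = np.empty(0, int)
        self.p_subj = subj

        # per-pair, per-mode constants of the analytic effect-site response
        self._a = []  # rate * A / lam
        self._lam = []
        self._e_lam_tc = []  # exp(-lam * tau_c)
        self._one_m_lam = []  # 1 - exp(-lam * tau_c)
        self._e_lam_u = []  # exp(-lam * u)
        tau_c = np.clip(tau, 0.0, dur)
        u = np.maximum(tau - dur, 0.0)
        self._tau_c = tau_c
        self._u = u
        for lam_s, coef_s in ((lam1, a1), (lam2, a2)):
            lam = lam_s[subj]
            a = rate * coef_s[subj] / lam
            self._lam.append(lam)
            self._a.append(a)
            self._e_lam_tc.append(np.exp(-lam * tau_c))
            self._one_m_lam.append(-np.expm1(-lam * tau_c))
            self._e_lam_u.append(np.exp(-lam * u))

    def effect_site(self, ke0_by_subject: np.ndarray) -> np.ndarray:
        """Ce at every observation given one ke0 per subject."""
        ke0 = np.asarray(ke0_by_subject, dtype=float)[self.p_subj]
        e_ke0_tc = np.exp(-ke0 * self._tau_c)
        e_ke0_u = np.exp(-ke0 * self._u)
        one_m_ke0 = 1.0 - e_ke0_tc
        total = np.zeros(len(ke0))
        for a, lam, e_lam_tc, one_m_lam, e_lam_u in zip(
            self._a, self._lam, self._e_lam_tc, self._one_m_lam, self._e_lam_u
        ):
            safe = np.abs(ke0 - lam) > 1e-9 * np.maximum(lam, 1.0)
            w = ke0 / np.where(safe, ke0 - lam, 1.0)
            ce_end = a * (one_m_ke0 - w * (e_lam_tc - e_ke0_tc))
            total += ce_end * e_ke0_u + a * one_m_lam * w * (e_lam_u - e_ke0_u)
        return np.bincount(self.p_obs, weights=total, minlength=self.n_obs)

    def predict(self, psi: np.ndarray, ce: np.ndarray | None = None):
        """Predicted scores for transformed parameters ``psi`` (n, 4).

        psi columns: (log ke0_i, log e0_i, log deff_i, kprog_i).  Returns
        ``(scores, ce)`` so callers can reuse the effect-site vector.
        """
        if ce is None:
            ce = self.effect_site(np.exp(psi[:, 0]))
        s = self.obs_subject
        f = np.exp(psi[s, 1]) + psi[s, 3] * self.obs_time + np.exp(psi[s, 2]) * ce
        return f, ce

    def rss_by_subject(self, residuals: np.ndarray) -> np.ndarray:
        return np.bincount(
            self.obs_subject, weights=residuals**2, minlength=self.n_subjects
        )

    @property
    def nobs_by_subject(self) -> np.ndarray:
        return np.bincount(self.obs_subject, minlength=self.n_subjects)
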