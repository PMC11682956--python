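"""Virtual pediatric populations and trial dataset simulation.

Emulates the statistical structure of the phase-II study: ~145 children
aged 2-11 years (82.8% male), three arms (placebo / low / high) with a
two-week half-dose titration in the high-dose arm, weight-tiered BID
dosing to week 24, placebo crossover to high dose at week 12, and score
observations at weeks 0/12/24/36 with additive residual error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .params import ModelParameters
from .pkpd import effect_site_from_regimen, score_model
from .population import individualize, sample_etas
from .regimen import DoseEvent, Regimen

__all__ = [
    "WeightBand",
    "PHASE2_BANDS",
    "PHASE3_BANDS",
    "TrialDesign",
    "TrialDataset",
    "phase2_design",
    "generate_population",
    "assign_weight_band_dose",
    "build_regimen",
    "simulate_dataset",
]


@dataclass(frozen=True)
class WeightBand:
    """Half-open weight interval [low, high) mapped to a per-administration dose."""

    low: float  # kg, inclusive
    high: float  # kg, exclusive (inf for the top band)
    dose_g: float  # grams per administration


# Phase-II weight-tiered full doses (high-dose arm; low arm receives half).
PHASE2_BANDS = (
    WeightBand(10, 15, 2),
    WeightBand(15, 25, 4),
    WeightBand(25, 38, 7),
    WeightBand(38, 52, 10),
    WeightBand(52, math.inf, 14),
)

# Weight-tiered doses proposed for the phase-III scenario simulations.
PHASE3_BANDS = (
    WeightBand(10, 14, 2),
    WeightBand(14, 21, 4),
    WeightBand(21, 35, 6),
    WeightBand(35, 50, 10),
    WeightBand(50, math.inf, 14),
)

ARMS = ("placebo", "low", "high")

# Sex-specific median weight (kg) by age (years), ages 2..12.  Plausible
# growth-chart medians; linear interpolation between integer ages.  The
# spread around the median is log-normal with a configurable CV.
_GROWTH_AGES = np.arange(2, 13, dtype=float)
_GROWTH_MEDIAN_KG = {
    "male": np.array([12.7, 14.3, 16.3, 18.4, 20.7, 23.1, 25.8, 28.7, 32.0, 35.6, 39.8]),
    "female": np.array([12.1, 13.9, 15.9, 17.9, 20.2, 22.8, 25.8, 29.0, 32.9, 36.9, 41.2]),
}


@dataclass(frozen=True)
class TrialDesign:
    """Arms, dosing rules and visit schedule of a (virtual) trial."""

    bands: tuple[WeightBand, ...] = PHASE2_BANDS
    arm_ratios: dict = field(
        default_factory=lambda: {"placebo": 1.0, "low": 1.0, "high": 1.0}
    )
    visit_days: tuple[float, ...] = (0.0, 84.0, 168.0, 252.0)
    treatment_end: float = 168.0  # last dosing day (exclusive)
    titration_days: float = 14.0  # half-dose run-in length (high arm)
    titration_factor: float = 0.5
    crossover_day: float | None = 84.0  # placebo -> high dose; None disables
    bid_interval: float = 0.5  # days between administrations
    dropout_prob: float = 0.0  # missing-at-random per post-baseline visit

    def __post_init__(self) -> None:
        if list(self.visit_days) != sorted(self.visit_days):
            raise ValueError("visit_days must be sorted")
        lows = [b.low for b in self.bands]
        highs = [b.high for b in self.bands]
        if lows != sorted(lows) or any(h != l for h, l in zip(highs[:-1], lows[1:])):
            raise ValueError("weight bands must partition the range without gaps")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must be in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "bands": [[b.low, None if math.isinf(b.high) else b.high, b.dose_g]
                      for b in self.bands],
            "arm_ratios": dict(self.arm_ratios),
            "visit_days": list(self.visit_days),
            "treatment_end": self.treatment_end,
            "titration_days": self.titration_days,
            "titration_factor": self.titration_factor,
            "crossover_day": self.crossover_day,
            "bid_interval": self.bid_interval,
            "dropout_prob": self.dropout_prob,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrialDesign":
        bands = tuple(
            WeightBand(low, math.inf if high is None else high, dose)
            for low, high, dose in d.get("bands", [])
        ) or PHASE2_BANDS
        kwargs = {k: d[k] for k in (
            "arm_ratios", "treatment_end", "titration_days", "titration_factor",
            "crossover_day", "bid_interval", "dropout_prob") if k in d}
        if "visit_days" in d:
            kwargs["visit_days"] = tuple(d["visit_days"])
        return cls(bands=bands, **kwargs)


def phase2_design(**overrides) -> TrialDesign:
    """The phase-II-shaped default design."""
    return replace(TrialDesign(), **overrides) if overrides else TrialDesign()


@dataclass
class TrialDataset:
    """Long-format trial data: demographics, dose events, observations."""

    demographics: pd.DataFrame  # id, age, weight, sex, arm, baseline_serine
    doses: pd.DataFrame  # id, time, amount_mg, duration
    observations: pd.DataFrame  # id, time, score, missing

    def __post_init__(self) -> None:
        ids = set(self.demographics["id"])
        for name in ("doses", "observations"):
            tab = getattr(self, name)
            unknown = set(tab["id"]) - ids
            if unknown:
                raise ValueError(f"{name} reference unknown subject ids {sorted(unknown)!r}")
        obs = self.observations
        present = obs[~obs["missing"]]
        missing_baseline = ids - set(present.loc[present["time"] == 0.0, "id"])
        if missing_baseline:
            raise ValueError(
                f"subjects without a baseline observation: {sorted(missing_baseline)!r}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.demographics)

    @property
    def n_observations(self) -> int:
        return int((~self.observations["missing"]).sum())

    def regimen_for(self, subject_id) -> Regimen:
        rows = self.doses[self.doses["id"] == subject_id]
        return Regimen(
            DoseEvent(r.time, r.amount_mg, r.duration)
            for r in rows.itertuples(index=False)
        )


def generate_population(
    n: int,
    age_range: tuple[float, float] = (2.0, 12.0),
    sex_male_fraction: float = 0.828,
    seed: int | np.random.Generator = 0,
    weight_cv: float = 0.15,
    weight_limits: tuple[float, float] = (10.0, 60.0),
    with_baseline_serine: bool = True,
) -> pd.DataFrame:
    """Sample correlated age-weight-sex demographics for ``n`` children.

    Ages are uniform on ``age_range``; weight is drawn around the
    sex-specific growth-table median at that age with log-normal spread
    ``weight_cv``, truncated (by redraw) to ``weight_limits``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = age_range
    if not (2.0 <= lo < hi <= 12.0):
        raise ValueError("age_range must be a nonempty interval within [2, 12]")
    rng = np.random.default_rng(seed)
    age = rng.uniform(lo, hi, size=n)
    sex = np.where(rng.uniform(size=n) < sex_male_fraction, "male", "female")
    median = np.empty(n)
    for s in ("male", "female"):
        m = sex == s
        median[m] = np.interp(age[m], _GROWTH_AGES, _GROWTH_MEDIAN_KG[s])
    sd_log = math.sqrt(math.log(1.0 + weight_cv**2))
    weight = median * np.exp(rng.standard_normal(n) * sd_log)
    for _ in range(100):  # redraw outside the growth envelope
        bad = (weight < weight_limits[0]) | (weight > weight_limits[1])
        if not bad.any():
            break
        weight[bad] = median[bad] * np.exp(rng.standard_normal(bad.sum()) * sd_log)
    weight = np.clip(weight, *weight_limits)
    demog = pd.DataFrame(
        {"id": np.arange(1, n + 1), "age": age, "weight": weight, "sex": sex}
    )
    if with_baseline_serine:
        # total serine, umol/L: median ~128 with a long right tail
        demog["baseline_serine"] = np.clip(
            128.0 * np.exp(rng.standard_normal(n) * 0.35), 70.0, 650.0
        )
    return demog


def assign_weight_band_dose(weight: float, band_table=PHASE3_BANDS) -> float:
    """Dose in grams per administration for ``weight`` kg (half-open bands)."""
    if weight < band_table[0].low:
        raise ValueError(
            f"weight {weight} kg is below the lowest band ({band_table[0].low} kg)"
        )
    for band in band_table:
        if band.low <= weight < band.high:
            return band.dose_g
    raise ValueError(f"weight {weight} kg not covered by the band table")


def build_regimen(
    arm: str, weight: float, design: TrialDesign, dose_duration: float
) -> Regimen:
    """BID dose-event list for one subject.

    high: half dose during titration, full dose to treatment end.
    low: half dose throughout.  placebo: nothing until the crossover day,
    then titration + full dose to treatment end (if crossover is enabled).
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    full = assign_weight_band_dose(weight, design.bands)
    half = full * design.titration_factor
    events: list[DoseEvent] = []
    bid = lambda g, t0, t1: Regimen.bid(g, t0, t1, dose_duration, design.bid_interval)
    if arm == "high":
        events += bid(half, 0.0, design.titration_days)
        events += bid(full, design.titration_days, design.treatment_end)
    elif arm == "low":
        events += bid(full * 0.5, 0.0, design.treatment_end)
    elif arm == "placebo" and design.crossover_day is not None:
        t0 = design.crossover_day
        events += bid(half, t0, t0 + design.titration_days)
        events += bid(full, t0 + design.titration_days, design.treatment_end)
    return Regimen(events)


def _allocate_arms(n: int, ratios: dict, rng: np.random.Generator) -> np.ndarray:
    names = [a for a in ARMS if ratios.get(a, 0) > 0]
    w = np.array([ratios[a] for a in names], dtype=float)
    w = w / w.sum()
    counts = np.floor(w * n).astype(int)
    # largest-remainder rounding
    rem = w * n - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    arms = np.repeat(names, counts)
    return rng.permutation(arms)


def simulate_dataset(
    design: TrialDesign,
    params: ModelParameters,
    n: int = 145,
    seed: int | np.random.Generator = 0,
    demographics: pd.DataFrame | None = None,
) -> TrialDataset:
    """Simulate a complete trial dataset under the generative model.

    For each subject: draw etas, individualise parameters, build the
    arm's regimen, evaluate the effect-site concentration at the visit
    days, apply the score model and add residual error.  Deterministic
    given the seed.
    """
    rng = np.random.default_rng(seed)
    if demographics is None:
        demographics = generate_population(n, age_range=(2.0, 11.0), seed=rng)
    else:
        demographics = demographics.reset_index(drop=True).copy()
        n = len(demographics)
    if "arm" not in demographics.columns:
        demographics["arm"] = _allocate_arms(n, design.arm_ratios, rng)
    etas = sample_etas(params.ranef, n, rng)
    visits = np.asarray(design.visit_days, dtype=float)
    dose_rows, obs_rows = [], []
    for i, row in enumerate(demographics.itertuples(index=False)):
        ind = individualize(params.pk, params.pd, etas[i], row.age, row.weight)
        regimen = build_regimen(row.arm, row.weight, design, params.pk.d1)
        pk_i = params.pk.scaled_to(row.weight)
        ce = effect_site_from_regimen(ind.ke0_i, pk_i, regimen, visits)
        pred = score_model(ind.e0_i, ind.kprog_i, ind.deff_i, ce, visits)
        scores = pred + rng.standard_normal(len(visits)) * params.ranef.sigma_add
        miss = np.zeros(len(visits), dtype=bool)
        if design.dropout_prob > 0:
            miss[1:] = rng.uniform(size=len(visits) - 1) < design.dropout_prob
        for e in regimen:
            dose_rows.append((row.id, e.start, e.amount_mg, e.duration))
        for t, s, m in zip(visits, scores, miss):
            obs_rows.append((row.id, t, np.nan if m else s, m))
    doses = pd.DataFrame(dose_rows, columns=["id", "time", "amount_mg", "duration"])
    observations = pd.DataFrame(obs_rows, columns=["id", "time", "score", "missing"])
    return TrialDataset(demographics=demographics, doses=doses, observations=observations)
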