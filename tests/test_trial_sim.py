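"""Dose-scenario engine: deltas, attainment, dose-banding, forest ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from serinepkpd import (
    ModelParameters,
    PDParameters,
    RandomEffectSpec,
    WeightBand,
    compare_fixed_vs_mgkg,
    delta_score,
    forest_ratios,
    mgkg_range,
    phase2_design,
    run_dose_scenarios,
    simulate_dataset,
    target_attainment,
)
from serinepkpd.population import sample_etas
from serinepkpd.scenarios import _simulate_deltas
from serinepkpd.trial import generate_population

from conftest import make_demographics


class TestDeltaScore:
    def test_identical_scores_give_zero(self, noise_free_params):
        demog = make_demographics([5.0], [20.0], ["placebo"])
        p = ModelParameters(
            pk=noise_free_params.pk,
            pd=PDParameters(ke0=0.0065, e0=48.51, beta_age=-0.21, deff=0.0022,
                            kprog=0.0),
            ranef=RandomEffectSpec(0, 0, 0, 0, 0.0, 0.0),
        )
        ds = simulate_dataset(phase2_design(crossover_day=None), p, seed=1,
                              demographics=demog)
        assert delta_score(ds).iloc[0] == pytest.approx(0.0)

    def test_deterministic_placebo_delta(self, noise_free_params):
        demog = make_demographics([5.0], [20.0], ["placebo"])
        ds = simulate_dataset(phase2_design(crossover_day=None),
                              noise_free_params, seed=1, demographics=demog)
        assert delta_score(ds).iloc[0] == pytest.approx(1.26)

    def test_subject_missing_a_visit_is_excluded(self, params, caplog):
        ds = simulate_dataset(phase2_design(dropout_prob=0.4), params, n=30, seed=3)
        with caplog.at_level("INFO", logger="serinepkpd.scenarios"):
            deltas = delta_score(ds)
        n_with_both = ds.observations[
            (~ds.observations["missing"]) & (ds.observations["time"] == 84.0)
        ]["id"].nunique()
        assert len(deltas) == n_with_both
        assert "excluding" in caplog.text


class TestTargetAttainment:
    def test_all_above(self):
        assert target_attainment([3.0, 3.0, 3.0]) == 100.0

    def test_strict_inequality_at_boundary(self):
        assert target_attainment([1.0, 2.0, 3.0]) == pytest.approx(100.0 / 3.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            target_attainment([])

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=40))
    @settings(max_examples=50, derandomize=True)
    def test_bounds(self, deltas):
        pct = target_attainment(deltas)
        assert 0.0 <= pct <= 100.0


class TestMgkgRange:
    @pytest.mark.parametrize(
        "dose, lo, hi, expected",
        [
            (2.0, 10.0, 13.0, (308, 400)),
            (4.0, 14.0, 20.0, (400, 571)),
            (1.0, 1000.0, 1000.0, (2, 2)),
        ],
    )
    def test_examples(self, dose, lo, hi, expected):
        assert mgkg_range(dose, lo, hi) == expected

    def test_positive_weights_required(self):
        with pytest.raises(ValueError):
            mgkg_range(2.0, 0.0, 10.0)


class TestDoseScenarios:
    def test_median_delta_monotone_in_dose(self, params):
        band = (WeightBand(14, 21, 4),)
        table = run_dose_scenarios(
            params, band_table=band, dose_levels=[2.0, 6.0, 14.0],
            n_per_band=150, seed=3,
        )
        treated = table[table["arm"] == "treated"].sort_values("dose_g_bid")
        assert treated["p50"].is_monotonic_increasing
        assert (
            treated["attainment_pct"].iloc[-1] > treated["attainment_pct"].iloc[0]
        )

    def test_treated_attainment_exceeds_placebo(self, params):
        table = run_dose_scenarios(params, n_per_band=150, seed=5)
        for band, grp in table.groupby("band"):
            treated = grp[grp["arm"] == "treated"]["attainment_pct"].iloc[0]
            placebo = grp[grp["arm"] == "placebo"]["attainment_pct"].iloc[0]
            assert treated > placebo, band

    def test_null_drug_effect_makes_arms_identical(self, params):
        null = ModelParameters(
            pk=params.pk,
            pd=PDParameters(ke0=0.0065, e0=48.51, beta_age=-0.21, deff=0.0,
                            kprog=0.015),
            ranef=RandomEffectSpec(0.21, 0.2, 0.0, 0.018, 0.48, 1.6),
        )
        table = run_dose_scenarios(null, n_per_band=100, seed=7)
        for band, grp in table.groupby("band"):
            t = grp[grp["arm"] == "treated"].iloc[0]
            p = grp[grp["arm"] == "placebo"].iloc[0]
            # same subjects, same etas and residuals, zero drug slope
            for col in ("p5", "p50", "p95", "attainment_pct"):
                assert t[col] == pytest.approx(p[col]), (band, col)

    def test_uncertainty_layer_widens_bands(self, params):
        kw = dict(n_per_band=150, seed=9)
        base = run_dose_scenarios(params, include_uncertainty=False, **kw)
        unc = run_dose_scenarios(params, include_uncertainty=True, **kw)
        w_base = (base["p95"] - base["p5"])[base["arm"] == "treated"].sum()
        w_unc = (unc["p95"] - unc["p5"])[unc["arm"] == "treated"].sum()
        assert w_unc >= w_base

    def test_percentile_ordering_and_attainment_bounds(self, params):
        table = run_dose_scenarios(params, n_per_band=60, seed=11,
                                   include_uncertainty=True)
        assert (table["p5"] <= table["p50"]).all()
        assert (table["p50"] <= table["p95"]).all()
        assert table["attainment_pct"].between(0, 100).all()

    def test_doubling_deff_doubles_drug_attributable_delta(self, params):
        band = (WeightBand(21, 35, 6),)

        def med_drug_effect(factor):
            p = ModelParameters(
                pk=params.pk,
                pd=PDParameters(ke0=0.0065, e0=48.51, beta_age=-0.21,
                                deff=0.0022 * factor, kprog=0.015),
                ranef=params.ranef,
            )
            t = run_dose_scenarios(p, band_table=band, n_per_band=400, seed=13)
            treated = t[t["arm"] == "treated"]["p50"].iloc[0]
            placebo = t[t["arm"] == "placebo"]["p50"].iloc[0]
            return treated - placebo

        one, two = med_drug_effect(1.0), med_drug_effect(2.0)
        assert two == pytest.approx(2 * one, rel=0.25)


class TestFixedVsMgkg:
    def test_exact_equivalence_at_matching_weight(self, params):
        """2 g BID for a 10 kg child is exactly 200 mg/kg BID: identical
        regimens and shared noise give identical deltas."""
        demog = make_demographics([4.0, 4.0], [10.0, 10.0], ["high", "high"])
        rng = np.random.default_rng(3)
        etas = sample_etas(params.ranef, 2, rng)
        noise = rng.standard_normal((2, 2)) * params.ranef.sigma_add
        fixed = _simulate_deltas(demog, lambda w: 2.0, params,
                                 np.random.default_rng(1), etas=etas, noise=noise)
        perkg = _simulate_deltas(demog, lambda w: 200.0 * w / 1000.0, params,
                                 np.random.default_rng(2), etas=etas, noise=noise)
        assert np.array_equal(fixed, perkg)

    def test_paired_difference_small_relative_to_spread(self, params):
        table = compare_fixed_vs_mgkg(params, n_per_band=150, seed=15)
        assert (table["median_paired_diff"].abs() < table["delta_iqr"]).all()


class TestForestRatios:
    def test_reference_bin_ratio_is_one(self, params):
        table = forest_ratios(params, n=600, seed=17, n_boot=40)
        ref = table[table["is_reference"]]
        assert np.allclose(ref["ratio"], 1.0)

    def test_no_iiv_cl_ratio_follows_allometry(self, noise_free_params):
        n = 800
        table = forest_ratios(noise_free_params, n=n, seed=19, n_boot=10)
        demog = generate_population(n, age_range=(2.0, 12.0),
                                    seed=np.random.default_rng(19))
        cl_rows = table[(table["covariate"] == "weight") & (table["parameter"] == "cl")]
        ref_row = cl_rows[cl_rows["is_reference"]].iloc[0]
        lo, hi = ref_row["bin"].strip("[)").split(",")
        in_ref = demog["weight"].between(float(lo), float(hi), inclusive="left")
        w_ref = demog[in_ref]["weight"].median()
        for _, row in cl_rows.iterrows():
            lo, hi = row["bin"].strip("[)").split(",")
            m = demog["weight"].between(float(lo), float(hi), inclusive="left")
            # median interpolation on even counts makes this approximate
            expected = (demog[m]["weight"].median() / w_ref) ** 0.75
            assert row["ratio"] == pytest.approx(expected, rel=1e-3)

    def test_younger_bins_have_higher_baseline_with_negative_age_exponent(
        self, noise_free_params
    ):
        table = forest_ratios(noise_free_params, n=800, seed=21, n_boot=10)
        e0_age = table[(table["covariate"] == "age") & (table["parameter"] == "e0")]
        youngest = e0_age.iloc[0]
        assert youngest["ratio"] > 1.0
        assert (e0_age["ratio"].diff().dropna() <= 0).all()
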