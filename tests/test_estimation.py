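"""Mixed-effects estimation: likelihood, fitting, LRT, bootstrap, covariates."""

import numpy as np
import pytest

from serinepkpd import (
    CovariateEffect,
    ModelParameters,
    PDParameters,
    RandomEffectSpec,
    SaemOptions,
    bootstrap,
    covariate_search,
    fit,
    gof_table,
    lrt_decision,
    neg2_loglik,
    phase2_design,
    simulate_dataset,
)
from serinepkpd.trial import TrialDesign

from conftest import make_demographics


class TestLrtDecision:
    def test_threshold_semantics(self):
        dec = lrt_decision(100.0, 103.85, df=1, alpha=0.05)
        assert dec.accept_full
        dec = lrt_decision(100.0, 103.80, df=1, alpha=0.05)
        assert not dec.accept_full

    def test_zero_drop_keeps_reduced(self):
        dec = lrt_decision(100.0, 100.0)
        assert not dec.accept_full
        assert dec.p_value == pytest.approx(1.0)

    def test_chi2_critical_value(self):
        assert lrt_decision(0.0, 0.0).critical == pytest.approx(3.84, abs=0.005)

    def test_non_nested_violation_raises(self):
        with pytest.raises(ValueError):
            lrt_decision(100.0, 95.0)


class TestNeg2Loglik:
    def test_degenerate_omega_limit_is_plain_gaussian(self, params):
        """With all etas removed the marginal likelihood collapses to the
        product of observation densities at the typical prediction."""
        ds = simulate_dataset(phase2_design(), params, n=15, seed=3)
        flat = ModelParameters(
            pk=params.pk, pd=params.pd,
            ranef=RandomEffectSpec(0, 0, 0, 0, 0.0, params.ranef.sigma_add),
        )
        ofv = neg2_loglik(flat, ds)
        gof = gof_table(ds, flat)
        sigma = params.ranef.sigma_add
        resid = (gof["observed"] - gof["pred"]).to_numpy()
        expected = np.sum(resid**2 / sigma**2) + len(resid) * np.log(
            2 * np.pi * sigma**2
        )
        assert ofv == pytest.approx(expected, rel=1e-10)

    def test_laplace_matches_quadrature_oracle(self, params):
        """3-subject toy with a single E0 random effect: Laplace vs exact
        Gauss-Hermite integration of the marginal likelihood."""
        demog = make_demographics([4.0, 6.0, 9.0], [16.0, 20.0, 28.0],
                                  ["placebo"] * 3)
        toy = ModelParameters(
            pk=params.pk, pd=params.pd,
            ranef=RandomEffectSpec(0, 0.15, 0, 0, 0.0, 1.5),
        )
        design = TrialDesign(visit_days=(0.0, 84.0, 168.0), crossover_day=None)
        ds = simulate_dataset(design, toy, seed=5, demographics=demog)

        ofv = neg2_loglik(toy, ds)

        # brute-force oracle: for placebo subjects the prediction is
        # e0_typ(age) * exp(eta) + kprog * t
        nodes, weights = np.polynomial.hermite_e.hermegauss(201)
        obs = ds.observations
        total = 0.0
        for sid, row in zip(demog["id"], demog.itertuples(index=False)):
            y = obs[obs["id"] == sid].sort_values("time")
            t = y["time"].to_numpy()
            yv = y["score"].to_numpy()
            e0_typ = toy.pd.e0 * (row.age / 5.0) ** toy.pd.beta_age
            lik = 0.0
            for z, w in zip(nodes, weights):
                eta = 0.15 * z
                f = e0_typ * np.exp(eta) + toy.pd.kprog * t
                dens = np.prod(
                    np.exp(-0.5 * ((yv - f) / 1.5) ** 2) / (1.5 * np.sqrt(2 * np.pi))
                )
                lik += w * dens
            total += -2.0 * np.log(lik / np.sqrt(2 * np.pi))
        assert ofv == pytest.approx(total, abs=0.1)

    def test_requires_positive_sigma(self, params, small_dataset):
        bad = ModelParameters(
            pk=params.pk, pd=params.pd,
            ranef=RandomEffectSpec(0.1, 0.1, 0.1, 0.01, 0.0, 0.0),
        )
        with pytest.raises(ValueError):
            neg2_loglik(bad, small_dataset)


class TestFit:
    def test_zero_noise_dataset_recovers_fixed_effects_exactly(self, params, noise_free_params):
        """Deterministic inversion: no IIV, no residual error -> the fixed
        effects come back to at least 4 significant digits."""
        ds = simulate_dataset(phase2_design(), noise_free_params, n=24, seed=9)
        start = ModelParameters(
            pk=params.pk,
            pd=PDParameters(ke0=0.01, e0=45.0, beta_age=-0.1, deff=0.001, kprog=0.01),
            ranef=RandomEffectSpec(0, 0, 0, 0, 0.0, 0.0),
        )
        res = fit(ds, init=start, pk=params.pk, method="laplace")
        assert res.method == "laplace"
        for name, truth in [
            ("ke0", 0.0065), ("e0", 48.51), ("beta_age", -0.21),
            ("deff", 0.0022), ("kprog", 0.015),
        ]:
            assert res.estimates[name] == pytest.approx(truth, rel=1e-4), name

    def test_saem_is_reproducible_given_seed(self, params, small_dataset, fast_saem):
        kw = dict(pk=params.pk, seed=42, saem_options=fast_saem, polish=False,
                  compute_ofv=False)
        a = fit(small_dataset, **kw)
        b = fit(small_dataset, **kw)
        assert a.estimates == b.estimates
        assert a.omegas == b.omegas
        assert a.sigma_add == b.sigma_add

    def test_nesting_full_model_ofv_not_worse(self, params, small_dataset, fast_saem):
        kw = dict(pk=params.pk, seed=7, saem_options=fast_saem)
        reduced = fit(small_dataset, covariates=(), **kw)
        full = fit(small_dataset, covariates=(CovariateEffect("e0", "age", 5.0),), **kw)
        assert full.ofv <= reduced.ofv + 0.5

    def test_fit_ofv_not_worse_than_truth(self, params, small_dataset, fast_saem):
        res = fit(small_dataset, pk=params.pk, seed=11, saem_options=fast_saem)
        assert res.ofv <= neg2_loglik(params, small_dataset) + 2.0

    def test_standard_errors_finite_and_positive(self, params, fast_saem):
        ds = simulate_dataset(phase2_design(), params, n=20, seed=31)
        res = fit(ds, pk=params.pk, seed=2, saem_options=fast_saem, compute_se=True)
        assert res.se is not None
        for name in ("ke0", "e0", "deff", "kprog", "sigma_add"):
            assert np.isfinite(res.se[name]) and res.se[name] > 0, name
        assert res.rse_percent["e0"] < 50.0  # baseline is precisely estimated


class TestBootstrap:
    def test_identity_resample_reproduces_original_fit(self, params, noise_free_params):
        ds = simulate_dataset(phase2_design(), noise_free_params, n=15, seed=13)
        start = ModelParameters(
            pk=params.pk,
            pd=PDParameters(ke0=0.01, e0=45.0, beta_age=-0.1, deff=0.001, kprog=0.01),
            ranef=RandomEffectSpec(0, 0, 0, 0, 0.0, 0.0),
        )
        original = fit(ds, init=start, pk=params.pk, method="laplace")
        boot = bootstrap(ds, n_runs=1, seed=5, identity_first=True,
                         init=start, pk=params.pk, method="laplace")
        assert boot.replicates.loc[0, "kprog"] == pytest.approx(
            original.estimates["kprog"], rel=1e-8
        )
        assert boot.n_converged == 1

    def test_percentiles_bracket_median(self, params, small_dataset):
        boot = bootstrap(
            small_dataset, n_runs=3, seed=17, pk=params.pk,
            saem_options=SaemOptions(n_burn=40, n_smooth=20), polish=False,
            compute_ofv=False,
        )
        assert len(boot.replicates) == 3
        assert (boot.ci_low <= boot.median).all()
        assert (boot.median <= boot.ci_high).all()


class TestCovariateSearch:
    def test_true_age_effect_is_retained(self, params, fast_saem):
        ds = simulate_dataset(phase2_design(), params, n=60, seed=23)
        res = covariate_search(
            ds,
            candidates=[CovariateEffect("e0", "age", 5.0)],
            pk=params.pk, seed=3, saem_options=fast_saem,
        )
        assert [(c.param, c.covariate) for c in res.selected] == [("e0", "age")]
        assert any(step["step"] == "backward" for step in res.log)

    def test_null_covariate_not_retained(self, params, fast_saem):
        no_age = ModelParameters(
            pk=params.pk,
            pd=PDParameters(ke0=0.0065, e0=48.51, beta_age=0.0, deff=0.0022,
                            kprog=0.015),
            ranef=params.ranef,
        )
        ds = simulate_dataset(phase2_design(), no_age, n=45, seed=29)
        res = covariate_search(
            ds,
            candidates=[CovariateEffect("e0", "weight", None)],
            pk=params.pk, seed=4, saem_options=fast_saem,
        )
        assert res.selected == ()

    def test_empty_candidates_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            covariate_search(small_dataset, candidates=[])
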