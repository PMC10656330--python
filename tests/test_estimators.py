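"""Estimator API, posterior summaries, and small recovery fits."""

import numpy as np
import pytest
from sklearn.base import clone

from drsm.estimators import (
    DRSM,
    ERSIRTree,
    FitResult,
    FlexibleDRSM,
    MCMCConfig,
    OrdinalIRTree,
    PriorSpec,
    StaticIRTree,
    TwoPLIRTree,
    check_convergence,
    credible_interval,
    eap,
    make_model,
)
from drsm._model import build_model, variant_slots
from drsm.simulate import SimulationCondition, simulate_dataset
from drsm.tree import AGREE_TRAIT, EXTREME_ERS, EXTREME_TRAIT, MODERATE_MRS


def _dummy_fit(draws_dict, **overrides):
    kwargs = dict(
        variant="drsm",
        draws=draws_dict,
        rhat={},
        max_rhat=1.0,
        converged=True,
        loglik=None,
        obs_index=None,
        accept_stat=np.array([0.9]),
        divergences=np.zeros(1, dtype=int),
        n_persons=1,
        n_items=1,
        config=MCMCConfig(),
    )
    kwargs.update(overrides)
    return FitResult(**kwargs)


class TestSklearnInterface:
    def test_get_set_params_and_clone(self):
        est = DRSM(chains=2, warmup=10, draws=10, random_state=3)
        params = est.get_params()
        assert params["chains"] == 2 and params["random_state"] == 3
        est2 = clone(est).set_params(warmup=20)
        assert est2.warmup == 20 and est2.chains == 2
        assert est2.variant == "drsm"

    def test_make_model_name_normalization(self):
        assert isinstance(make_model("F-DRSM"), FlexibleDRSM)
        assert isinstance(make_model("2pl"), TwoPLIRTree)
        assert isinstance(make_model("ERS"), ERSIRTree)
        with pytest.raises(ValueError):
            make_model("graded")

    def test_mcmc_config_validation(self):
        with pytest.raises(ValueError):
            MCMCConfig(chains=1)
        assert MCMCConfig.simulation_preset().draws == 500
        assert MCMCConfig.empirical_preset().draws == 1000


class TestVariantSlots:
    def test_loading_constraint_table(self):
        ordinal = variant_slots("ordinal")
        assert ordinal[EXTREME_TRAIT].kind == "fixed" and ordinal[EXTREME_TRAIT].value == 1.0
        assert ordinal[EXTREME_ERS].value == 0.0
        ers = variant_slots("ers")
        assert ers[EXTREME_TRAIT].value == 0.0 and ers[EXTREME_ERS].value == 1.0
        static = variant_slots("static")
        assert static[EXTREME_TRAIT].kind == "constant"
        drsm = variant_slots("drsm")
        assert drsm[EXTREME_TRAIT].kind == "trajectory"
        assert drsm[AGREE_TRAIT].kind == "fixed"  # Rasch agreement node
        drsm2 = variant_slots("drsm", agreement="model")
        assert drsm2[AGREE_TRAIT].kind == "trajectory"
        fdrsm = variant_slots("fdrsm", agreement="model", has_moderate=True)
        assert fdrsm[MODERATE_MRS].kind == "noisy"

    def test_eta_kappa_inclusion_follows_slots(self, drsm_small_dataset):
        data = drsm_small_dataset.data
        assert not build_model(data, "ordinal").include_eta
        assert build_model(data, "ers").include_eta
        assert build_model(data, "drsm").include_eta

    def test_prior_spec_threads_through(self, drsm_small_dataset):
        est = DRSM(priors=PriorSpec(loading_sd=1.0, cauchy_scale=2.5))
        from drsm._model import _Priors

        pr = est.priors
        assert pr.loading_sd == 1.0
        m = build_model(drsm_small_dataset.data, "drsm",
                        priors=_Priors(loading_sd=1.0, cauchy_scale=2.5))
        assert m.priors.cauchy_scale == 2.5


class TestPosteriorSummaries:
    def test_constant_draws_give_degenerate_summaries(self):
        fr = _dummy_fit({"x": np.full((2, 10), 3.5)})
        assert eap(fr, "x") == pytest.approx(3.5)
        lo, hi = credible_interval(fr, "x")
        assert lo == hi == pytest.approx(3.5)

    def test_normal_draws_recover_standard_interval(self):
        rng = np.random.default_rng(8)
        fr = _dummy_fit({"x": rng.standard_normal((4, 25_000))})
        lo, hi = credible_interval(fr, "x", level=0.95)
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)
        assert eap(fr, "x") == pytest.approx(0.0, abs=0.02)

    def test_check_convergence_threshold(self):
        good = _dummy_fit({"x": np.zeros((2, 4))}, max_rhat=1.01)
        bad = _dummy_fit({"x": np.zeros((2, 4))}, max_rhat=1.2, converged=False)
        assert check_convergence(good)["passed"]
        report = check_convergence(bad)
        assert not report["passed"]
        assert check_convergence(bad, threshold=1.3)["passed"]


class TestFitting:
    def test_incompatible_categories_rejected(self):
        cond = SimulationCondition(
            variant="drsm", N=30, I=8, n_categories=5,
            trait_trajectory=(0.8, 0.2), ers_trajectory=(0.3, 0.7), base_seed=70,
        )
        sim = simulate_dataset(cond, 0)
        with pytest.raises(ValueError, match="outside 1..4"):
            OrdinalIRTree(n_categories=4, warmup=10, draws=10).fit(sim.data.responses)

    def test_functional_front_end_returns_fit_result(self, drsm_small_dataset):
        from drsm.estimators import fit

        fr = fit("ordinal", drsm_small_dataset.data,
                 mcmc=MCMCConfig(chains=2, warmup=40, draws=40))
        assert isinstance(fr, FitResult)
        assert fr.variant == "ordinal"
        assert "theta" in fr.draws and fr.loglik is not None

    def test_ordinal_model_recovers_trait_ranking(self):
        cond = SimulationCondition(variant="ordinal", N=250, I=12, base_seed=71)
        sim = simulate_dataset(cond, 0)
        est = OrdinalIRTree(chains=4, warmup=250, draws=250, random_state=0)
        est.fit(sim.data)
        assert est.converged_
        r = np.corrcoef(est.theta_[:, 0], sim.person.theta[:, 0])[0, 1]
        assert r > 0.8
        assert "eta" not in est.result_.draws  # trait-only model

    def test_drsm_fit_exposes_trajectories_and_score(self, drsm_fit, drsm_small_dataset):
        est = drsm_fit
        tr = est.trajectories_
        assert set(tr) == {EXTREME_TRAIT, EXTREME_ERS}
        for slot in tr:
            ci = tr[slot]["slope_ci"]
            assert ci.shape == (2, 1)
            assert ci[0] <= tr[slot]["slope"] <= ci[1]
        # trajectory truth: trait decreases, ERS increases
        assert tr[EXTREME_TRAIT]["slope"] < 0
        assert tr[EXTREME_ERS]["slope"] > 0
        assert np.isfinite(est.score())
        assert est.beta_.shape == (2, drsm_small_dataset.data.n_items)

    def test_shape_posterior_wider_than_endpoints(self, drsm_fit):
        """The trajectory shape is weakly identified relative to its endpoints."""
        fr = drsm_fit.result_
        for slot in (EXTREME_TRAIT, EXTREME_ERS):
            sd_lam = fr.posterior_sd(f"lam.{slot}")
            sd_g1 = fr.posterior_sd(f"gamma_first.{slot}")
            sd_gI = fr.posterior_sd(f"gamma_last.{slot}")
            assert sd_lam > sd_g1
            assert sd_lam > sd_gI


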