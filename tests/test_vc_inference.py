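"""Bayesian LMM fits and the per-draw variance statistics."""

import numpy as np
import pandas as pd
import pytest

from pigekit.phenotype_model import VarianceConfig, draw_genetic_effects, simulate_lifespans
from pigekit.vc_inference import (
    BayesLMM,
    ConfoundingError,
    MCMCConfig,
    ModelSpec,
    fit_lmm,
    group_variance_per_draw,
    residual_variance,
    summarize,
)

from conftest import make_design, one_way_data


def _simulate(seed=0, **cfg_kw):
    design = make_design()
    cfg = VarianceConfig(V_D=0.0, V_I=9.0, V_vial=2.0, V_R=40.0, check_interval=0,
                         n_genomes=4, **cfg_kw)
    eff = draw_genetic_effects(cfg, seed=seed, genomes=tuple(design["group"].unique()))
    return simulate_lifespans(design, eff, cfg, seed=seed + 1)


class TestModelSpec:
    @pytest.mark.parametrize(
        "mid,formula",
        [
            ("M1", "lifespan_days ~ group + (1|vial_id)"),
            ("M2", "lifespan_days ~ group * clone_type + (1|vial_id)"),
            ("M3", "lifespan_days ~ block + (1|group) + (1|vial_id)"),
        ],
    )
    def test_formulas(self, mid, formula):
        assert ModelSpec.from_id(mid).formula() == formula

    def test_unknown_id(self):
        with pytest.raises(ValueError):
            ModelSpec.from_id("M9")


class TestMCMCConfig:
    def test_default_retained_draws(self):
        assert MCMCConfig().n_draws == 4 * (4000 - 1000) == 12000

    def test_warmup_must_be_smaller(self):
        with pytest.raises(ValueError):
            MCMCConfig(iterations=100, warmup=100)


class TestFitLMM:
    def test_method_of_moments_oracle(self, quick_mcmc):
        # balanced one-way: posterior means of V_vial and V_R near the ANOVA
        # method-of-moments estimates computed from scratch here
        df = one_way_data(q=50, m=25, v_between=9.0, v_within=25.0, seed=11)
        y = df["lifespan_days"].to_numpy().reshape(50, 25)
        ym = y.mean(axis=1)
        msb = 25 * ym.var(ddof=1)
        msw = ((y - ym[:, None]) ** 2).sum() / (50 * 24)
        mom_vial, mom_r = (msb - msw) / 25, msw

        spec = ModelSpec(fixed=(), random=("vial_id",), model_id="oneway")
        est = BayesLMM(spec, chains=2, iterations=1500, warmup=500, seed=3,
                       compute_rhat=False).fit(df)
        assert (est.draws_.scales["sd_vial_id"] ** 2).mean() == pytest.approx(mom_vial, rel=0.15)
        assert est.residual_variance().mean() == pytest.approx(mom_r, rel=0.05)

    def test_reml_cross_check(self, quick_mcmc):
        # independent oracle: statsmodels MixedLM (REML) on the same data
        sm = pytest.importorskip("statsmodels.regression.mixed_linear_model")
        df = one_way_data(q=40, m=20, v_between=16.0, v_within=36.0, seed=21)
        fit = sm.MixedLM(df["lifespan_days"], np.ones((len(df), 1)),
                         groups=df["vial_id"]).fit(reml=True)
        spec = ModelSpec(fixed=(), random=("vial_id",), model_id="oneway")
        est = BayesLMM(spec, chains=2, iterations=1500, warmup=500, seed=4,
                       compute_rhat=False).fit(df)
        assert (est.draws_.scales["sd_vial_id"] ** 2).mean() == pytest.approx(
            float(fit.cov_re.iloc[0, 0]), rel=0.2)
        assert est.residual_variance().mean() == pytest.approx(float(fit.scale), rel=0.05)

    def test_degenerate_residual_matches_sample_variance(self, quick_mcmc):
        # single group, V_vial = 0: residual posterior ~ total sample variance
        df = one_way_data(q=10, m=40, v_between=0.0, v_within=30.0, seed=31)
        spec = ModelSpec(fixed=(), random=("vial_id",), model_id="oneway")
        est = BayesLMM(spec, **quick_mcmc, seed=5).fit(df)
        sample_var = df["lifespan_days"].var(ddof=1)
        assert est.residual_variance().mean() == pytest.approx(sample_var, rel=0.1)

    def test_default_budget_retains_12000_draws(self):
        df = one_way_data(q=6, m=5, seed=41)
        spec = ModelSpec(fixed=(), random=("vial_id",), model_id="oneway")
        draws = fit_lmm(df, spec)  # default MCMCConfig
        assert draws.n_draws == 12000
        assert draws.rhat  # diagnostics attached

    def test_missing_factor_column_raises(self, quick_mcmc):
        df = one_way_data(q=6, m=5).drop(columns=["group"])
        with pytest.raises(KeyError, match="group"):
            BayesLMM("M1", **quick_mcmc).fit(df)

    def test_single_level_factor_raises(self, quick_mcmc):
        df = one_way_data(q=6, m=5)  # group is constant "A"
        with pytest.raises(ValueError, match="levels"):
            BayesLMM("M1", **quick_mcmc).fit(df)

    def test_confounded_design_raises(self, quick_mcmc):
        df = one_way_data(q=6, m=5)
        df["group"] = np.where(df["vial_id"] < "v003", "A", "B")
        df["clone_type"] = df["group"].map({"A": "PIGE_clone", "B": "PTGE_clone"})
        # clone_type duplicates group exactly -> singular fixed design
        spec = ModelSpec(fixed=("group", "clone_type"), random=("vial_id",), model_id="bad")
        with pytest.raises(ConfoundingError):
            BayesLMM(spec, **quick_mcmc).fit(df)

    def test_sklearn_params_round_trip(self):
        est = BayesLMM("M2", chains=3, seed=7)
        params = est.get_params()
        clone = BayesLMM(**params)
        assert clone.get_params() == params


class TestGroupVariancePerDraw:
    def test_brute_force_oracle(self, quick_mcmc):
        data = _simulate(seed=50)
        est = BayesLMM("M1", **quick_mcmc, seed=6).fit(data)
        draws = est.draws_
        stat = group_variance_per_draw(draws, "group")
        # independent recomputation: loop over draws, rebuild level means from
        # the raw coefficient table
        df = draws.to_dataframe()
        levels = draws.fixed_levels["group"]
        expected = np.empty(len(df))
        for r in range(len(df)):
            means = []
            for lev in levels:
                m = df["(Intercept)"].iloc[r]
                col = f"group[{lev}]"
                if col in df.columns:
                    m += df[col].iloc[r]
                means.append(m)
            expected[r] = np.var(means, ddof=1)
        np.testing.assert_allclose(stat, expected, rtol=1e-6)

    def test_forced_denominator_k_minus_1(self):
        # a draw with level means {60, 62, 64, 66} must give 20/3
        assert np.var([60, 62, 64, 66], ddof=1) == pytest.approx(20 / 3)

    def test_two_groups_equals_half_squared_difference(self, quick_mcmc):
        data = _simulate(seed=60)
        data = data[data["group"].isin(["A", "B"])]
        est = BayesLMM("M1", **quick_mcmc, seed=7).fit(data)
        stat = group_variance_per_draw(est.draws_, "group")
        diff = est.draws_._coef("group[B]")
        np.testing.assert_allclose(stat, diff**2 / 2, rtol=1e-10)

    def test_location_invariance_exact(self, quick_mcmc):
        data = _simulate(seed=70)
        shifted = data.assign(lifespan_days=data["lifespan_days"] + 1000.0)
        a = BayesLMM("M1", **quick_mcmc, seed=8).fit(data)
        b = BayesLMM("M1", **quick_mcmc, seed=8).fit(shifted)
        np.testing.assert_allclose(
            group_variance_per_draw(a.draws_, "group"),
            group_variance_per_draw(b.draws_, "group"),
            rtol=1e-8,
        )

    def test_m2_subsets_give_both_components(self, quick_mcmc):
        design = pd.concat(
            [make_design(clone_type="PIGE_clone"), make_design(clone_type="PTGE_clone")],
            ignore_index=True,
        )
        design["vial_id"] = design["clone_type"].str[:4] + "_" + design["vial_id"]
        cfg = VarianceConfig(V_D=20.0, V_I=4.0, V_vial=2.0, V_R=40.0, check_interval=0)
        eff = draw_genetic_effects(cfg, seed=80, genomes=tuple(design["group"].unique()))
        data = simulate_lifespans(design, eff, cfg, seed=81)
        est = BayesLMM("M2", **quick_mcmc, seed=9).fit(data)
        v_gi = group_variance_per_draw(est.draws_, "group", subset="PIGE_clone")
        v_gdi = group_variance_per_draw(est.draws_, "group", subset="PTGE_clone")
        # PTGE-clones express d+i, PIGE-clones only i: more variance among PTGE means
        assert v_gdi.mean() > v_gi.mean()

    def test_interaction_requires_subset(self, quick_mcmc):
        design = pd.concat(
            [make_design(clone_type="PIGE_clone"), make_design(clone_type="PTGE_clone")],
            ignore_index=True,
        )
        design["vial_id"] = design["clone_type"].str[:4] + "_" + design["vial_id"]
        cfg = VarianceConfig(check_interval=0)
        eff = draw_genetic_effects(cfg, seed=1, genomes=tuple(design["group"].unique()))
        data = simulate_lifespans(design, eff, cfg, seed=2)
        est = BayesLMM("M2", **quick_mcmc, seed=10).fit(data)
        with pytest.raises(ValueError, match="interaction"):
            group_variance_per_draw(est.draws_, "group")

    def test_unknown_factor_raises(self, quick_mcmc):
        data = _simulate(seed=90)
        est = BayesLMM("M1", **quick_mcmc, seed=11).fit(data)
        with pytest.raises(KeyError):
            group_variance_per_draw(est.draws_, "sex")


class TestResidualVariance:
    def test_elementwise_square_of_sigma(self, quick_mcmc):
        data = _simulate(seed=100)
        est = BayesLMM("M1", **quick_mcmc, seed=12).fit(data)
        sigma = est.draws_.scales["sigma"]
        np.testing.assert_allclose(residual_variance(est.draws_), sigma**2, rtol=0)

    def test_constant_sigma_gives_zero_spread(self):
        from pigekit.vc_inference import PosteriorDraws

        d = PosteriorDraws(
            spec=ModelSpec(), mcmc=MCMCConfig(), coef_names=["(Intercept)"],
            beta=np.zeros((5, 1)), fixed_levels={}, random={}, random_levels={},
            scales={"sigma": np.full(5, 10.0)}, chain_id=np.zeros(5), iter_id=np.arange(5),
            rhat={},
        )
        rv = residual_variance(d)
        assert np.all(rv == 100.0) and rv.std() == 0.0


class TestSummarize:
    def test_constant_vector(self):
        s = summarize(np.full(100, 3.5))
        assert (s.mean, s.ci_low, s.ci_high) == (3.5, 3.5, 3.5)

    def test_small_vector_mean(self):
        assert summarize(np.array([1.0, 2.0, 3.0])).mean == pytest.approx(2.0)

    def test_normal_quantiles(self):
        rng = np.random.default_rng(0)
        s = summarize(rng.standard_normal(2_000_000))
        assert s.ci_low == pytest.approx(-1.96, abs=0.01)
        assert s.ci_high == pytest.approx(1.96, abs=0.01)

    def test_empty_vector_raises(self):
        with pytest.raises(ValueError):
            summarize(np.array([]))


class TestParameterRecoveryProperty:
    def test_among_population_recovery(self):
        """Known-variance simulations land inside the 95% CI in most replicates.

        Scaled-down counterpart of the paper-scale recovery check in the
        acceptance suite: 8 genomes, 12 replicates, reduced sampler budget.
        With few genomes the realized among-genome variance differs from the
        observed group-mean variance by a sampling-covariance term, so
        coverage of the realized value sits slightly below nominal; the floor
        here is 9/12 per component.
        """
        groups = tuple("ABCDEFGH")
        cover_i = cover_di = 0
        n_rep = 12
        for rep in range(n_rep):
            design = make_design(groups=groups, n_vials=10, per_vial=20)
            design2 = make_design(groups=groups, clone_type="PTGE_clone",
                                  n_vials=10, per_vial=20)
            design2["vial_id"] = "P_" + design2["vial_id"]
            cfg = VarianceConfig(V_D=16.0, V_I=9.0, V_vial=2.0, V_R=40.0,
                                 check_interval=0, n_genomes=8)
            eff = draw_genetic_effects(cfg, seed=200 + rep, genomes=groups)
            pige = simulate_lifespans(design, eff, cfg, seed=300 + rep)
            ptge = simulate_lifespans(design2, eff, cfg, seed=400 + rep)
            true_i = np.var(eff.i, ddof=1)
            true_di = np.var(eff.d + eff.i, ddof=1)
            for data, truth, which in ((pige, true_i, "i"), (ptge, true_di, "di")):
                est = BayesLMM("M1", chains=2, iterations=800, warmup=200,
                               seed=500 + rep, compute_rhat=False).fit(data)
                s = summarize(group_variance_per_draw(est.draws_, "group"))
                hit = s.ci_low <= truth <= s.ci_high
                if which == "i":
                    cover_i += hit
                else:
                    cover_di += hit
        assert cover_i >= 9
        assert cover_di >= 9
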