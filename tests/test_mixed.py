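import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from conftest import build_cohort, random_valid_cohort
from donorhb import (
    CohortConfig,
    LMEParams,
    empirical_bayes,
    fit_lme,
    fit_ols,
    icc,
    lrt_random_slope,
    predict_dynamic_lme,
    reml_criterion,
    simulate_lme_cohort,
)
from donorhb import reference as ref
from donorhb.results import FitResult
from oracles import dense_reml


def _ri_params(s2b0, s2e, alpha=9.4, beta=(-0.004, -0.06, -0.05)):
    return LMEParams(alpha=alpha, beta=beta, sigma2_b0=s2b0, sigma2_b1=None,
                     sigma2_eps=s2e, structure="RI")


class TestOLS:
    def test_exact_recovery_on_noise_free_plane(self):
        rng = np.random.default_rng(0)
        coh = random_valid_cohort(rng, n_donors=6)
        df = coh.data
        df["hb"] = 9.4 - 0.004 * df.age - 0.06 * df.season - 0.05 * df.dpv
        fit = fit_ols(coh)
        assert fit.params.alpha == pytest.approx(9.4, abs=1e-9)
        assert np.allclose(fit.params.beta, (-0.004, -0.06, -0.05), atol=1e-9)

    def test_equals_normal_equations(self, lme_small):
        fit = fit_ols(lme_small)
        df = lme_small.data
        X = np.column_stack(
            [np.ones(len(df)), df[["age", "season", "dpv"]].to_numpy()]
        )
        coef = np.linalg.solve(X.T @ X, X.T @ df.hb.to_numpy())
        assert fit.params.alpha == pytest.approx(coef[0], abs=1e-8)
        assert np.allclose(fit.params.beta, coef[1:], atol=1e-8)


class TestREMLCriterion:
    def test_matches_dense_matrix_oracle_ri(self):
        coh = build_cohort(
            [("a", 1, 30.0, 0, 0, 1, 9.2), ("a", 2, 30.2, 1, 1, 0, 9.6),
             ("a", 3, 30.4, 0, 0, 0, 8.9),
             ("b", 1, 45.0, 1, 0, 0, 8.7), ("b", 2, 45.2, 0, 0, 1, 9.0),
             ("b", 3, 45.4, 1, 1, 1, 9.1)]
        )
        p = _ri_params(0.12, 0.25)
        assert reml_criterion(p, coh) == pytest.approx(
            dense_reml(np.array([0.12]), 0.25, coh, "RI"), abs=1e-10
        )

    @pytest.mark.parametrize("structure", ["RI", "RIRS"])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_dense_matrix_oracle_random(self, structure, seed):
        rng = np.random.default_rng(seed)
        coh = random_valid_cohort(rng, n_donors=6, t_max=5)
        assert coh.n_obs <= 30
        d = np.array([0.1, 2e-4])
        p = LMEParams(
            alpha=9.4, beta=(0, 0, 0), sigma2_b0=d[0],
            sigma2_b1=d[1] if structure == "RIRS" else None,
            sigma2_eps=0.3, structure=structure,
        )
        assert reml_criterion(p, coh) == pytest.approx(
            dense_reml(d, 0.3, coh, structure), abs=1e-10
        )

    def test_zero_variances_reduce_to_error_only_model(self):
        rng = np.random.default_rng(2)
        coh = random_valid_cohort(rng, n_donors=5)
        p = _ri_params(0.0, 0.3)
        df = coh.data
        n = len(df)
        X = np.column_stack(
            [np.ones(n), df[["age", "season", "dpv"]].to_numpy()]
        )
        y = df.hb.to_numpy()
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        r = y - X @ beta
        s2 = 0.3
        expect = -0.5 * (
            n * math.log(s2)
            + np.linalg.slogdet(X.T @ X / s2)[1]
            + r @ r / s2
            + (n - 4) * math.log(2 * math.pi)
        )
        assert reml_criterion(p, coh) == pytest.approx(expect, abs=1e-10)

    def test_duplicating_a_donor_adds_its_contribution(self):
        rng = np.random.default_rng(3)
        coh = random_valid_cohort(rng, n_donors=4)
        p = _ri_params(0.1, 0.3)
        dup = coh.data[coh.data.donor_id == "d000"].copy()
        dup["donor_id"] = "d999"
        from donorhb.panel import Cohort

        bigger = Cohort(pd.concat([coh.data, dup]), "M")
        # the dense oracle must agree on the enlarged cohort too
        assert reml_criterion(p, bigger) == pytest.approx(
            dense_reml(np.array([0.1]), 0.3, bigger, "RI"), abs=1e-10
        )


class TestFitLME:
    def test_ri_agrees_with_statsmodels(self, lme_small):
        from statsmodels.regression.mixed_linear_model import MixedLM

        mine = fit_lme(lme_small, "RI")
        md = MixedLM.from_formula(
            "hb ~ age + season + dpv", groups="donor_id", data=lme_small.data
        )
        mf = md.fit(reml=True)
        assert mine.params.alpha == pytest.approx(mf.params.iloc[0], rel=1e-3)
        assert np.allclose(mine.params.beta, mf.params.values[1:4], rtol=1e-3,
                           atol=1e-6)
        assert mine.params.sigma2_b0 == pytest.approx(
            float(mf.cov_re.iloc[0, 0]), rel=1e-3
        )
        assert mine.params.sigma2_eps == pytest.approx(mf.scale, rel=1e-3)
        assert mine.extras["reml"] == pytest.approx(mf.llf, abs=1e-4)

    def test_rirs_criterion_validates_against_statsmodels(self, lme_small_female):
        # diagonal-D random slope: the criterion evaluated at the reference
        # implementation's solution must reproduce its restricted loglik, and
        # this package's optimum must be at least as good
        from statsmodels.regression.mixed_linear_model import MixedLM

        mine = fit_lme(lme_small_female, "RIRS")
        md = MixedLM.from_formula(
            "hb ~ age + season + dpv", groups="donor_id",
            vc_formula={"ic": "1", "slope": "0 + age"}, re_formula="0",
            data=lme_small_female.data,
        )
        mf = md.fit(reml=True)
        at_sm = LMEParams(
            alpha=0.0, beta=(0, 0, 0), sigma2_b0=float(mf.vcomp[0]),
            sigma2_b1=float(mf.vcomp[1]), sigma2_eps=float(mf.scale),
            structure="RIRS",
        )
        assert reml_criterion(at_sm, lme_small_female) == pytest.approx(
            mf.llf, abs=1e-4
        )
        assert mine.extras["reml"] >= mf.llf - 1e-6

    def test_boundary_variance_reported_as_zero(self):
        params = _ri_params(0.0, 0.25)
        cfg = CohortConfig(n_donors=150, gender="M", seed=40)
        coh = simulate_lme_cohort(params, cfg)
        fit = fit_lme(coh, "RI")
        if fit.extras["boundary"][0]:
            assert fit.params.sigma2_b0 == 0.0
        else:
            assert fit.params.sigma2_b0 < 0.01

    def test_recovery_coverage_across_replicates(self):
        truth = {
            "alpha": 9.6719, "beta_age": -0.0049, "beta_season": -0.0698,
            "beta_dpv": -0.0636, "sigma2_b0": 0.1225, "sigma2_eps": 0.2025,
        }
        n_rep = 100
        hits = {k: 0 for k in truth}
        for s in range(n_rep):
            cfg = CohortConfig(n_donors=120, gender="M", seed=6_000 + s)
            coh = simulate_lme_cohort(ref.MALE_LME_RI, cfg)
            fit = fit_lme(coh, "RI")
            p = fit.params
            est = {
                "alpha": p.alpha, "beta_age": p.beta[0],
                "beta_season": p.beta[1], "beta_dpv": p.beta[2],
                "sigma2_b0": p.sigma2_b0, "sigma2_eps": p.sigma2_eps,
            }
            for k in truth:
                if abs(est[k] - truth[k]) <= 3 * fit.se[k]:
                    hits[k] += 1
        for k, h in hits.items():
            assert h >= 0.95 * n_rep, (k, h)


class TestEmpiricalBayes:
    def test_empty_prefix_returns_prior_mean(self):
        p = _ri_params(0.1, 0.3)
        est = empirical_bayes(p, pd.DataFrame(columns=["donor_id", "hb"]))
        assert est.b0_hat == 0.0 and est.b1_hat == 0.0 and est.n_used == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ri_matches_shrinkage_formula(self, seed):
        rng = np.random.default_rng(seed)
        coh = random_valid_cohort(rng, n_donors=1, t_max=7)
        prefix = coh.data
        s2b0, s2e = float(rng.uniform(0.05, 0.5)), float(rng.uniform(0.1, 0.5))
        p = _ri_params(s2b0, s2e)
        est = empirical_bayes(p, prefix)
        x = prefix[["age", "season", "dpv"]].to_numpy()
        resid = prefix.hb.to_numpy() - p.alpha - x @ np.array(p.beta)
        n = len(prefix)
        expect = n * s2b0 / (n * s2b0 + s2e) * resid.mean()
        assert est.b0_hat == pytest.approx(expect, abs=1e-10)

    def test_large_prior_variance_gives_mean_residual(self):
        rng = np.random.default_rng(3)
        coh = random_valid_cohort(rng, n_donors=1)
        p = _ri_params(1e8, 0.3)
        est = empirical_bayes(p, coh.data)
        x = coh.data[["age", "season", "dpv"]].to_numpy()
        resid = coh.data.hb.to_numpy() - p.alpha - x @ np.array(p.beta)
        assert est.b0_hat == pytest.approx(resid.mean(), rel=1e-6)

    def test_shrinkage_monotone_in_noise_variance(self):
        rng = np.random.default_rng(4)
        coh = random_valid_cohort(rng, n_donors=1)
        mags = [
            abs(empirical_bayes(_ri_params(0.1, s2e), coh.data).b0_hat)
            for s2e in (0.05, 0.2, 0.8, 3.2)
        ]
        assert mags == sorted(mags, reverse=True)


class TestPredictDynamicLME:
    def test_first_visit_is_fixed_effects_only(self, lme_small):
        p = ref.MALE_LME_RI
        pred = predict_dynamic_lme(p, lme_small).data
        first_mask = lme_small.data.visit == 1
        x = lme_small.data[first_mask][["age", "season", "dpv"]].to_numpy()
        expect = p.alpha + x @ np.array(p.beta)
        assert np.allclose(pred.y_pred[first_mask.to_numpy()], expect, atol=1e-12)

    def test_second_visit_matches_conditional_bivariate_normal(self):
        coh = build_cohort(
            [("a", 1, 30.0, 0, 0, 1, 9.9), ("a", 2, 30.2, 1, 1, 0, 9.1)]
        )
        p = _ri_params(0.12, 0.25)
        pred = predict_dynamic_lme(p, coh).data
        x = coh.data[["age", "season", "dpv"]].to_numpy()
        m = p.alpha + x @ np.array(p.beta)
        rho = 0.12 / (0.12 + 0.25)
        expect = m[1] + rho * (9.9 - m[0])
        assert pred.y_pred.iloc[1] == pytest.approx(expect, abs=1e-10)

    def test_zero_variance_coincides_with_ols_predictions(self, lme_small):
        fit = fit_ols(lme_small)
        p_lr = fit.params
        p_ri = LMEParams(
            alpha=p_lr.alpha, beta=p_lr.beta, sigma2_b0=0.0, sigma2_b1=None,
            sigma2_eps=p_lr.sigma2_eps, structure="RI",
        )
        a = predict_dynamic_lme(p_lr, lme_small).data
        b = predict_dynamic_lme(p_ri, lme_small).data
        assert np.allclose(a.y_pred, b.y_pred, atol=1e-12)

    def test_matches_sequential_empirical_bayes(self, lme_small_female):
        # vectorized prefix solver == visit-by-visit EB on a few donors
        p = ref.FEMALE_LME_RIRS
        pred = predict_dynamic_lme(p, lme_small_female).data
        df = lme_small_female.data
        for did in list(df.donor_id.unique())[:3]:
            g = df[df.donor_id == did].reset_index(drop=True)
            for t in range(1, len(g) + 1):
                est = empirical_bayes(p, g.iloc[: t - 1])
                row = g.iloc[t - 1]
                expect = (
                    p.alpha + est.b0_hat
                    + (p.beta[0] + est.b1_hat) * row.age
                    + p.beta[1] * row.season + p.beta[2] * row.dpv
                )
                got = pred[(pred.donor_id == did) & (pred.visit == t)].y_pred.iloc[0]
                assert got == pytest.approx(expect, abs=1e-9)


class TestICCAndLRT:
    def test_icc_values(self):
        assert icc(_ri_params(1.0, 3.0)) == 0.25
        assert icc(_ri_params(0.0, 3.0)) == 0.0
        assert icc(_ri_params(2.0, 2.0)) == 0.5
        p = LMEParams(alpha=9, beta=(0, 0, 0), sigma2_b0=0.1, sigma2_b1=1e-4,
                      sigma2_eps=0.2, structure="RIRS")
        with pytest.raises(ValueError):
            icc(p)

    def _fake_fit(self, model, loglik, n_obs=100):
        return FitResult(params=None, se={}, loglik=loglik, n_obs=n_obs,
                         n_params=6, converged=True, n_iter=1, model=model)

    def test_mixture_pvalue_formula(self):
        ri = self._fake_fit("LME-RI", -100.0)
        rirs = self._fake_fit("LME-RIRS", -100.0)
        assert lrt_random_slope(ri, rirs) == (0.0, 1.0)
        rirs = self._fake_fit("LME-RIRS", -98.5)  # L = 3.0
        L, p = lrt_random_slope(ri, rirs)
        assert L == pytest.approx(3.0)
        assert p == pytest.approx(0.5 * (chi2.sf(3.0, 1) + chi2.sf(3.0, 2)), abs=1e-12)

    def test_pvalue_strictly_decreasing_in_statistic(self):
        ri = self._fake_fit("LME-RI", -100.0)
        ps = [
            lrt_random_slope(ri, self._fake_fit("LME-RIRS", -100.0 + L / 2))[1]
            for L in (0.5, 2.0, 8.0, 30.0)
        ]
        assert ps == sorted(ps, reverse=True)
        assert ps[-1] < 1e-5

    def test_mismatched_cohorts_rejected(self):
        ri = self._fake_fit("LME-RI", -100.0, n_obs=100)
        rirs = self._fake_fit("LME-RIRS", -99.0, n_obs=101)
        with pytest.raises(ValueError):
            lrt_random_slope(ri, rirs)
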