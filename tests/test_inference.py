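import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from glp1alc.inference import (
    CANDIDATE_STRUCTURES,
    candidate_fits,
    effect_table,
    extrapolate_controls,
    fit_glmm,
    power_rm_anova,
    select_by_bic,
)
from glp1alc.synthetic import CohortSpec, generate_cohort, tlfb_long


def small_cohort(seed=0, n=(30, 30, 30), **kw):
    return tlfb_long(generate_cohort(CohortSpec(n_per_group=n, seed=seed, **kw)))


ZERO_RE = dict(random_intercept_sd=0.0)


class TestFitGlmm:
    def test_gaussian_intercept_only_is_grand_mean(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "participant": np.repeat([f"P{i}" for i in range(10)], 2),
                "group": "control",
                "time": np.tile([0, 1], 10),
                "y": rng.normal(5.0, 1.0, 20),
            }
        )
        fit = fit_glmm(df, "y", "gaussian", fixed=())
        assert fit.params["intercept"] == pytest.approx(df["y"].mean(), abs=1e-6)

    def test_poisson_zero_variance_matches_glm(self):
        """At sigma -> 0 the marginal likelihood must collapse to the plain
        Poisson GLM (IRLS oracle); on data generated without heterogeneity
        the full fit agrees with the GLM at sampling-noise level."""
        import statsmodels.api as sm

        df = small_cohort(seed=3, **ZERO_RE)
        fit = fit_glmm(df, "drinks", "poisson")
        from glp1alc.inference import _design, _gh_negloglik_factory

        y = df["drinks"].to_numpy(float)
        X, names, groups = _design(df, fit.fixed, "participant", "time", "group")
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        # exact oracle: quadrature likelihood at the sigma = 0 profile
        nll = _gh_negloglik_factory(y, X, groups, "poisson")
        ll_profile = -nll(np.append(glm.params, np.log(1e-10)))[0]
        assert ll_profile == pytest.approx(glm.llf, abs=1e-6)
        # full fit: variance estimate near the boundary, coefficients at
        # GLM values up to the tiny absorbed heterogeneity
        assert fit.sigma_u < 0.1
        assert np.allclose(fit.params.to_numpy(), glm.params, atol=5e-3)

    def test_bic_formula(self):
        df = small_cohort(seed=4)
        fit = fit_glmm(df, "drinks", "poisson", fixed=("group", "time"))
        assert fit.bic == pytest.approx(
            -2 * fit.loglik + fit.n_params * np.log(fit.n_obs), abs=1e-12
        )

    def test_family_validation(self):
        df = small_cohort(seed=5)
        df["bad"] = df["drinks"] + 0.5
        with pytest.raises(ValueError, match="integer"):
            fit_glmm(df, "bad", "poisson")
        with pytest.raises(ValueError, match="0/1"):
            fit_glmm(df, "drinks", "binomial")
        with pytest.raises(ValueError, match="family"):
            fit_glmm(df, "drinks", "negbin")

    def test_interaction_requires_main_effects(self):
        df = small_cohort(seed=6)
        with pytest.raises(ValueError, match="interaction"):
            fit_glmm(df, "drinks", "poisson", fixed=("group:time",))

    def test_matches_lme4_glmer(self, tmp_path):
        """Independent cross-check of the Poisson random-intercept fit
        against lme4's adaptive Gauss-Hermite implementation."""
        df = small_cohort(seed=7, n=(20, 20, 20))
        csv = tmp_path / "tlfb.csv"
        df.assign(group=df["group"].astype(str)).to_csv(csv, index=False)
        out = tmp_path / "coef.csv"
        script = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$group <- factor(d$group, levels=c("control","semaglutide","tirzepatide"))
            m <- glmer(drinks ~ group + time + (1|participant), data=d,
                       family=poisson, nAGQ=25)
            write.csv(data.frame(b=fixef(m)), "{out}")
            """
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(out)["b"].to_numpy()
        fit = fit_glmm(df, "drinks", "poisson", fixed=("group", "time"))
        assert np.allclose(fit.params.to_numpy(), ref, atol=2e-3)


class TestSelection:
    def test_true_interaction_selected_at_large_n(self):
        picks = []
        for seed in range(3):
            df = small_cohort(seed=seed, n=(60, 60, 60))
            best, _ = select_by_bic(candidate_fits(df, "drinks", "poisson"))
            picks.append("group:time" in best.fixed)
        assert sum(picks) >= 2  # generating model carries a real interaction

    def test_no_group_effect_prefers_smaller_model(self):
        coef = {
            "intercept": float(np.log(2.0)),
            "weekend": 0.6,
            "group": (0.0, 0.0),
            "group_x_weekend": (0.0, 0.0),
        }
        wins = 0
        for seed in range(3):
            df = small_cohort(seed=100 + seed, coef_drinks=coef)
            fits = {f.fixed: f for f in candidate_fits(df, "drinks", "poisson")}
            if fits[("time",)].bic < fits[("group", "time")].bic:
                wins += 1
        assert wins >= 2

    def test_single_candidate_returned(self):
        df = small_cohort(seed=8)
        fit = fit_glmm(df, "drinks", "poisson", fixed=("time",))
        best, ranking = select_by_bic([fit])
        assert best is fit and ranking == [fit]

    def test_candidate_set(self):
        assert CANDIDATE_STRUCTURES == (
            ("group",),
            ("time",),
            ("group", "time"),
            ("group", "time", "group:time"),
        )


class TestEffectTable:
    def _fit(self, family="poisson"):
        df = small_cohort(seed=9)
        outcome = "drinks" if family == "poisson" else "binge"
        return fit_glmm(df, outcome, family, fixed=("group", "time"))

    def test_exp_ci_arithmetic(self):
        fit = self._fit()
        fit.params["time"] = 0.0
        fit.se["time"] = 0.1
        row = effect_table(fit).set_index("term").loc["time"]
        assert row["irr"] == pytest.approx(1.0)
        assert row["irr_ci_low"] == pytest.approx(0.822, abs=5e-4)
        assert row["irr_ci_high"] == pytest.approx(1.217, abs=5e-4)

    def test_reported_weekend_irr(self):
        # exp arithmetic on the weekend coefficient scale: B=0.85, SE=0.07
        fit = self._fit()
        fit.params["time"] = 0.85
        fit.se["time"] = 0.07
        row = effect_table(fit).set_index("term").loc["time"]
        assert row["irr"] == pytest.approx(2.34, abs=5e-3)
        assert row["irr_ci_low"] == pytest.approx(2.04, abs=5e-3)
        assert row["irr_ci_high"] == pytest.approx(2.68, abs=5e-3)

    def test_gaussian_has_no_exp_column(self):
        df = small_cohort(seed=10)
        fit = fit_glmm(df, "drinks", "gaussian", fixed=("group", "time"))
        table = effect_table(fit)
        assert "irr" not in table.columns and "or" not in table.columns
        assert {"estimate", "se", "ci_low", "ci_high"} <= set(table.columns)


def simulate_rm_power(N, k, m, f, rho, alpha, n_reps=10_000, seed=0):
    """Monte-Carlo power of the within-factor repeated-measures F test:
    compound-symmetric subjects, time-point means with Cohen's f spread."""
    rng = np.random.default_rng(seed)
    delta = f  # for m=2, means (-d, +d) have population SD d against sigma=1
    mu = np.array([-delta, delta])
    subj = rng.normal(0, np.sqrt(rho), size=(n_reps, N, 1))
    eps = rng.normal(0, np.sqrt(1 - rho), size=(n_reps, N, m))
    y = mu + subj + eps
    group = np.repeat(np.arange(k), N // k)
    gm = y.mean(axis=(1, 2), keepdims=True)
    time_mean = y.mean(axis=1, keepdims=True)
    ss_time = N * ((time_mean - gm) ** 2).sum(axis=(1, 2))
    resid = y.copy()
    for g in range(k):
        sel = group == g
        yg = y[:, sel, :]
        resid[:, sel, :] = (
            yg
            - yg.mean(axis=2, keepdims=True)
            - yg.mean(axis=1, keepdims=True)
            + yg.mean(axis=(1, 2), keepdims=True)
        )
    ss_err = (resid**2).sum(axis=(1, 2))
    df1, df2 = m - 1, (N - k) * (m - 1)
    F = (ss_time / df1) / (ss_err / df2)
    from scipy import stats

    return float((F > stats.f.isf(alpha, df1, df2)).mean())


class TestPower:
    def test_reported_sample_size(self):
        N, achieved = power_rm_anova(0.25, 0.01, 0.95, 2, 2, rho=0.5, eps=1.0)
        assert N == 76
        assert achieved >= 0.95

    def test_monotone_in_effect_size(self):
        n_small, _ = power_rm_anova(0.25, 0.01, 0.95, 2, 2)
        n_large, _ = power_rm_anova(0.5, 0.01, 0.95, 2, 2)
        assert n_large < n_small

    def test_monotone_in_target_power(self):
        n_lo, _ = power_rm_anova(0.25, 0.01, 0.80, 2, 2)
        n_hi, _ = power_rm_anova(0.25, 0.01, 0.95, 2, 2)
        assert n_hi >= n_lo

    def test_monte_carlo_power_at_returned_n(self):
        N, _ = power_rm_anova(0.25, 0.01, 0.95, 2, 2, rho=0.5)
        emp = simulate_rm_power(N, k=2, m=2, f=0.25, rho=0.5, alpha=0.01)
        assert emp >= 0.95 - 0.01

    def test_invalid_request(self):
        with pytest.raises(ValueError):
            power_rm_anova(-0.1, 0.01, 0.95, 2, 2)
        with pytest.raises(ValueError):
            power_rm_anova(0.25, 0.01, 0.95, 2, 1)


class TestExtrapolateControls:
    @pytest.mark.parametrize("n,k,total", [(76, 2, 114), (10, 2, 15), (2, 2, 3)])
    def test_arithmetic(self, n, k, total):
        assert extrapolate_controls(n, k) == total

    def test_non_divisible_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            extrapolate_controls(7, 2)
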