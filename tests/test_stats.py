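"""Tests for the mixed-model and effect-size statistics."""

import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import binom

from cims import (
    GeneratorParams,
    apply_odds_ratio,
    binomial_variance,
    build_design,
    compare_models,
    fit_glmm,
    fit_variance_lmm,
    independent_t_test,
    marginal_expit,
    marginal_prevalence,
    odds_ratio,
    paired_t_test,
    simulate_trials,
)
from cims.stats import FixedTerm, GLMMFit, GLMMSpec


def _exp1_mcgurk(n_participants=24, seed=555, **gen_kwargs):
    design = build_design(1, {"n_participants": n_participants})
    defaults = dict(
        intercept=-0.1,
        condition_effects={"six_rep": 1.1, "control": 1.0},
        tau_participant=1.0,
        tau_stimulus=0.3,
        seed=seed,
    )
    defaults.update(gen_kwargs)
    t = simulate_trials(design, GeneratorParams(**defaults))
    return t[t.condition != "congruent"]


# ---------------------------------------------------------------------------
# GLMM estimation
# ---------------------------------------------------------------------------

class TestFitGLMM:
    def test_zero_variance_reduces_to_logistic_regression(self, exp1_table):
        """Pinning both variance components must reproduce the IRLS GLM."""
        t = exp1_table[exp1_table.condition != "congruent"]
        spec = GLMMSpec(fixed=(FixedTerm("group"), FixedTerm("condition")))
        fit = fit_glmm(t, spec, fix_variance={"participant_id": 0.0, "stimulus_id": 0.0})

        x = np.column_stack(
            [
                np.ones(len(t)),
                (t.group.astype(str) == "1").astype(float),
                (t.condition == "one_rep").astype(float),
                (t.condition == "six_rep").astype(float),
            ]
        )
        y = np.column_stack([t.n_da_tha, t.n_trials - t.n_da_tha])
        ref = sm.GLM(y, x, family=sm.families.Binomial()).fit()
        got = np.array(list(fit.coefficients.values()))
        assert np.allclose(got, ref.params, atol=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)
        assert np.allclose(list(fit.se.values()), ref.bse, atol=1e-5)

    def test_matches_lme4_glmer_oracle(self, tmp_path):
        """Independent cross-check of the Laplace ML fit against lme4."""
        t = _exp1_mcgurk(n_participants=30, seed=11, tau_participant=0.8, tau_stimulus=0.5,
                         intercept=-0.1, condition_effects={"six_rep": 1.0, "control": 1.0})
        csv = tmp_path / "trials.csv"
        t.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(lme4))
                d <- read.csv("{csv}")
                d$group <- factor(d$group)
                m <- glmer(cbind(n_da_tha, n_trials - n_da_tha) ~ group + condition +
                           (1 | participant_id) + (1 | stimulus_id),
                           data = d, family = binomial)
                out <- c(fixef(m), as.numeric(logLik(m)), BIC(m),
                         as.data.frame(VarCorr(m))$vcov)
                cat(sprintf("%.10f", out), sep = "\\n")
                """
            )
        )
        res = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert res.returncode == 0, res.stderr
        vals = [float(x) for x in res.stdout.split()]
        r_fixef, r_ll, r_bic, r_vc = vals[:4], vals[4], vals[5], vals[6:]

        spec = GLMMSpec(fixed=(FixedTerm("group"), FixedTerm("condition")))
        fit = fit_glmm(t, spec)
        assert np.allclose(list(fit.coefficients.values()), r_fixef, atol=0.01)
        assert fit.loglik == pytest.approx(r_ll, abs=0.02)
        assert fit.bic == pytest.approx(r_bic, abs=0.05)
        # same variance-component estimates (participant, stimulus order in R output)
        mine = [fit.variance_components["participant_id"], fit.variance_components["stimulus_id"]]
        assert np.allclose(sorted(mine), sorted(r_vc), atol=0.02)

    def test_bic_identity(self, exp1_table):
        t = exp1_table[exp1_table.condition != "congruent"]
        fit = fit_glmm(t, GLMMSpec(fixed=(FixedTerm("condition"),)))
        assert fit.bic == pytest.approx(
            fit.n_params * math.log(fit.n_obs) - 2 * fit.loglik, abs=1e-9
        )

    def test_null_effect_estimates_center_on_zero(self):
        """Small recovery study under a null condition effect."""
        rng = np.random.default_rng(17)
        design = build_design(1, {"n_participants": 20})
        spec = GLMMSpec(fixed=(FixedTerm("condition"),))
        est = []
        for _ in range(25):
            gen = GeneratorParams(
                intercept=0.2, condition_effects={}, tau_participant=1.0, tau_stimulus=0.0
            )
            t = simulate_trials(design, gen, rng=rng, include_congruent=False)
            t = t[t.condition.isin(["one_rep", "six_rep"])]
            est.append(fit_glmm(t, spec).coefficients["condition[six_rep]"])
        est = np.asarray(est)
        se = est.std(ddof=1) / math.sqrt(len(est))
        assert abs(est.mean()) < 3 * se

    def test_single_factor_agq_agrees_with_laplace(self):
        rng = np.random.default_rng(29)
        n_groups, n_per = 40, 8
        b = rng.normal(0, 1.0, n_groups)
        rows = []
        for g in range(n_groups):
            p = 1 / (1 + np.exp(-(0.3 + b[g])))
            rows.append(
                {
                    "participant_id": f"p{g}",
                    "stimulus_id": "s0",
                    "n_da_tha": rng.binomial(n_per, p),
                    "n_trials": n_per,
                }
            )
        t = pd.DataFrame(rows)
        spec = GLMMSpec(fixed=(), random=("participant_id",))
        laplace = fit_glmm(t, spec, n_agq=1)
        agq = fit_glmm(t, spec, n_agq=15)
        assert agq.coefficients["intercept"] == pytest.approx(
            laplace.coefficients["intercept"], abs=0.05
        )
        assert agq.variance_components["participant_id"] == pytest.approx(
            laplace.variance_components["participant_id"], rel=0.15
        )
        # AGQ refines the Laplace likelihood but must stay close
        assert agq.loglik == pytest.approx(laplace.loglik, abs=1.5)
        with pytest.raises(ValueError):
            fit_glmm(t, GLMMSpec(fixed=()), n_agq=5)  # two factors

    def test_input_validation(self, exp1_table):
        t = exp1_table[exp1_table.condition != "congruent"].copy()
        bad = t.copy()
        bad.loc[bad.index[0], "n_da_tha"] = bad.loc[bad.index[0], "n_trials"] + 1
        with pytest.raises(ValueError, match="binomial counts"):
            fit_glmm(bad, GLMMSpec())
        with pytest.raises(ValueError, match="random-intercept"):
            GLMMSpec(random=())


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def _dummy_fit(loglik, n_params, n_obs):
    return GLMMFit(
        coefficients={}, se={}, vcov=np.zeros((0, 0)), variance_components={},
        loglik=loglik, n_obs=n_obs, n_params=n_params,
        bic=n_params * math.log(n_obs) - 2 * loglik,
        converged=True, singular=False, message="", spec=GLMMSpec(),
    )


class TestCompareModels:
    def test_identical_bics(self):
        a, b = _dummy_fit(-100.0, 3, 50), _dummy_fit(-100.0, 3, 50)
        cmp_ = compare_models(a, b)
        assert cmp_.delta_bic == 0.0
        assert cmp_.approx_evidence_ratio == pytest.approx(1.0)
        assert not cmp_.decisive

    def test_delta_ten_gives_e_to_the_five(self):
        n_obs = 100
        a = _dummy_fit(-100.0, 3, n_obs)
        b = _dummy_fit(-100.0 + 5.0 + 0.5 * math.log(n_obs), 4, n_obs)  # dBIC exactly 10
        cmp_ = compare_models(a, b)
        assert cmp_.delta_bic == pytest.approx(10.0, abs=1e-9)
        assert cmp_.approx_evidence_ratio == pytest.approx(math.exp(5.0), rel=1e-9)
        assert cmp_.decisive

    def test_mismatched_data_rejected(self):
        with pytest.raises(ValueError, match="same data"):
            compare_models(_dummy_fit(-10, 2, 50), _dummy_fit(-10, 2, 60))

    def test_strong_effect_prefers_effect_model(self):
        t = _exp1_mcgurk(n_participants=40, seed=61, tau_stimulus=0.0,
                         condition_effects={"six_rep": 1.5, "control": 1.0})
        t = t[t.condition.isin(["one_rep", "six_rep"])]
        base = fit_glmm(t, GLMMSpec(fixed=(FixedTerm("group"),)))
        eff = fit_glmm(t, GLMMSpec(fixed=(FixedTerm("group"), FixedTerm("condition"))))
        assert compare_models(base, eff).preferred == "alternative"


# ---------------------------------------------------------------------------
# odds-ratio arithmetic
# ---------------------------------------------------------------------------

class TestOddsRatios:
    @pytest.mark.parametrize(
        "p_from,p_to,expected",
        [(0.1, 0.2, 2.25), (0.5, 0.6, 1.5)],
    )
    def test_worked_examples(self, p_from, p_to, expected):
        assert odds_ratio(p_from, p_to) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(0.01, 0.99))
    def test_identity(self, p):
        assert odds_ratio(p, p) == pytest.approx(1.0)

    @given(st.floats(0.02, 0.98), st.floats(0.02, 0.98))
    def test_round_trip(self, p, q):
        assert apply_odds_ratio(p, odds_ratio(p, q)) == pytest.approx(q, abs=1e-12)

    def test_apply_examples(self):
        assert apply_odds_ratio(0.5, 1.0) == pytest.approx(0.5)
        assert apply_odds_ratio(0.1, 2.25) == pytest.approx(0.2, abs=1e-12)
        assert apply_odds_ratio(0.49, 3.1) == pytest.approx(0.7487, abs=5e-4)

    def test_boundaries_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio(0.0, 0.5)
        with pytest.raises(ValueError):
            apply_odds_ratio(1.0, 2.0)
        with pytest.raises(ValueError):
            apply_odds_ratio(0.5, -1.0)


# ---------------------------------------------------------------------------
# marginal prevalence and binomial variance
# ---------------------------------------------------------------------------

class TestMarginalPrevalence:
    def test_zero_variance_is_conditional_expit(self):
        assert marginal_expit(1.3, [0.0, 0.0]) == pytest.approx(1 / (1 + math.exp(-1.3)))

    def test_symmetric_at_zero_predictor(self):
        for var in (0.5, 2.0, 9.0):
            assert marginal_expit(0.0, [var]) == pytest.approx(0.5, abs=1e-12)

    def test_matches_monte_carlo_integral(self):
        rng = np.random.default_rng(6)
        draws = rng.normal(0.0, 2.0, 1_000_000)  # variance 4
        mc = (1 / (1 + np.exp(-(1.0 + draws)))).mean()
        mc_se = (1 / (1 + np.exp(-(1.0 + draws)))).std() / 1000.0
        assert marginal_expit(1.0, [4.0]) == pytest.approx(mc, abs=3 * mc_se)

    def test_fit_interface_and_attenuation(self, exp1_table):
        t = exp1_table[exp1_table.condition != "congruent"]
        fit = fit_glmm(t, GLMMSpec(fixed=(FixedTerm("condition"),)))
        marg = marginal_prevalence(fit, {"condition": "six_rep"})
        cond = 1 / (1 + math.exp(-(fit.coefficients["intercept"]
                                   + fit.coefficients["condition[six_rep]"])))
        assert 0 < marg < 1
        # marginalization pulls an above-half probability toward 0.5
        if cond > 0.5:
            assert marg <= cond + 1e-9
        with pytest.raises(ValueError, match="covariates"):
            marginal_prevalence(fit, {})


class TestBinomialVariance:
    @pytest.mark.parametrize("n,p,expected", [(10, 0.5, 2.5), (10, 0.0, 0.0)])
    def test_closed_form(self, n, p, expected):
        assert binomial_variance(n, p) == expected

    def test_matches_pmf_enumeration(self):
        n, p = 20, 0.25
        ks = np.arange(n + 1)
        pmf = binom.pmf(ks, n, p)
        var = float(np.sum(pmf * ks**2) - np.sum(pmf * ks) ** 2)
        assert binomial_variance(n, p) == pytest.approx(var, abs=1e-10)
        assert binomial_variance(n, p) == pytest.approx(3.75)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_variance(10, 1.2)
        with pytest.raises(ValueError):
            binomial_variance(-1, 0.5)


# ---------------------------------------------------------------------------
# variance LMM (repetition precision analysis)
# ---------------------------------------------------------------------------

def _exp2_table(n_participants=20, seed=77, slope=0.0, rng=None):
    design = build_design(2, {"n_participants": n_participants})
    gen = GeneratorParams(
        intercept=0.4, repetition_slope=slope, tau_participant=1.2, tau_stimulus=0.2, seed=seed
    )
    t = simulate_trials(design, gen, rng=rng, include_congruent=False)
    return t


class TestVarianceLMM:
    def test_zero_variance_matches_ols(self):
        t = _exp2_table()
        fit = fit_variance_lmm(t, include_repetition_slope=True, fix_variance_zero=True)
        p_hat = t.n_da_tha / t.n_trials
        y = (t.n_trials * p_hat * (1 - p_hat)).to_numpy()
        x = np.column_stack([np.ones(len(t)), pd.to_numeric(t.condition).to_numpy(float)])
        ref = sm.OLS(y, x).fit()
        assert fit.coefficients["intercept"] == pytest.approx(ref.params[0], abs=1e-6)
        assert fit.slope == pytest.approx(ref.params[1], abs=1e-6)

    def test_flat_response_gives_zero_slope(self):
        """Variance varies across participants but not across repetition
        levels, so the fitted slope is ~0."""
        t = _exp2_table(seed=31)
        # overwrite counts so each participant's proportion is constant across levels
        rng = np.random.default_rng(2)
        prop = {pid: rng.uniform(0.2, 0.8) for pid in t.participant_id.unique()}
        t = t.assign(
            n_da_tha=[int(round(10 * prop[pid])) for pid in t.participant_id],
            n_trials=10,
        )
        t["n_ba"] = t.n_trials - t.n_da_tha
        t["n_ga"] = 0
        fit = fit_variance_lmm(t, include_repetition_slope=True)
        assert fit.slope == pytest.approx(0.0, abs=1e-4)

    def test_no_effect_bic_prefers_no_slope_model(self):
        """Under a generator without any repetition effect, the slope term is
        penalized away in the large majority of replicates."""
        rng = np.random.default_rng(130)
        wins = 0
        n_rep = 100
        for _ in range(n_rep):
            t = _exp2_table(n_participants=15, seed=None, rng=rng)
            base = fit_variance_lmm(t, include_repetition_slope=False)
            slope = fit_variance_lmm(t, include_repetition_slope=True)
            if compare_models(base, slope).preferred == "baseline":
                wins += 1
        assert wins >= 0.8 * n_rep


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

class TestTTests:
    def test_identical_vectors_give_zero_t(self):
        res = paired_t_test([0.2, 0.4, 0.6, 0.7], [0.2, 0.4, 0.6, 0.7])
        assert res.statistic == pytest.approx(0.0)
        assert res.df == 3

    def test_pooled_df_for_unequal_groups(self):
        rng = np.random.default_rng(0)
        res = independent_t_test(rng.normal(size=76), rng.normal(size=117), pooled=True)
        assert res.df == 191

    def test_matches_hand_computation(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([1.4, 1.9, 3.4, 4.4, 5.4])
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        res = paired_t_test(a, b)
        assert res.statistic == pytest.approx(t_hand, abs=1e-12)
        assert res.df == 4

    def test_welch_df_differs_from_pooled(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0, 5, 60)
        welch = independent_t_test(a, b, pooled=False)
        pooled = independent_t_test(a, b, pooled=True)
        assert welch.df != pooled.df

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0], [2.0])
        with pytest.raises(ValueError):
            independent_t_test([1.0], [1.0, 2.0])
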