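import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from betabursts.mixed import PoissonMixedGLM
from betabursts.simulate import SymptomGenSpec, gen_clinical_table
from betabursts.stats import (
    approx_bf,
    exceedance_prob,
    fit_feature_model,
    fit_rate_model,
    fit_symptom_models,
    pct_change,
    pct_change_inv,
)


def count_summaries(seed, n=19, pat_mean=106.0, ctl_mean=120.0, pat_sd=8.0, ctl_sd=11.0,
                    minutes=3.0, sessions=(1, 2)):
    """Per-subject/session burst-count table simulated directly."""
    rng = np.random.default_rng(seed)
    rows = []
    for g, mean, sd in [("patient", pat_mean, pat_sd), ("control", ctl_mean, ctl_sd)]:
        rates = np.clip(rng.normal(mean, sd, n), 0.0, None)
        for i, r in enumerate(rates):
            for sess in sessions:
                c = rng.poisson(r * minutes)
                rows.append(
                    {
                        "subject": f"{g[:3]}{i:02d}",
                        "group": g,
                        "session": sess,
                        "n_bursts": c,
                        "analyzed_s": minutes * 60.0,
                        "rate_per_min": c / minutes,
                    }
                )
    return pd.DataFrame(rows)


class TestPercentTransform:
    @given(st.floats(-0.5, 0.5))
    def test_roundtrip_exact(self, beta):
        assert pct_change_inv(pct_change(beta)) == pytest.approx(beta, abs=1e-12)

    def test_known_value(self):
        assert pct_change(np.log(0.72), per=1.0) == pytest.approx(-28.0)


class TestApproxBf:
    def test_model_against_itself_is_one(self):
        df = count_summaries(0)
        m = fit_rate_model(df).models["additive"]
        assert approx_bf(m, m) == 1.0

    def test_different_data_rejected(self):
        a = fit_rate_model(count_summaries(0)).models["additive"]
        b = fit_rate_model(count_summaries(1, n=10)).models["additive"]
        with pytest.raises(ValueError, match="different data"):
            approx_bf(a, b)

    def test_non_nested_rejected(self):
        X = np.column_stack([np.ones(40), np.arange(40.0)])
        y = np.random.default_rng(0).poisson(10, 40).astype(float)
        g = np.repeat(np.arange(20), 2)
        a = PoissonMixedGLM().fit(X, y, g, exog_names=["i", "a"])
        b = PoissonMixedGLM().fit(X, y, g, exog_names=["i", "b"])
        with pytest.raises(ValueError, match="nested"):
            approx_bf(a, b)

    def test_strong_planted_effect_conclusive(self):
        # 15% deficit, 50 subjects per group: strong evidence expected
        df = count_summaries(2, n=50, pat_mean=102.0, ctl_mean=120.0)
        assert fit_rate_model(df).bf_group > 3.0

    def test_null_effect_median_bf_below_one(self):
        bfs = [
            fit_rate_model(count_summaries(seed, pat_mean=113.0, ctl_mean=113.0,
                                           pat_sd=10.0, ctl_sd=10.0)).bf_group
            for seed in range(7)
        ]
        assert np.median(bfs) < 1.0


class TestExceedanceProb:
    def test_centered_samples_near_half(self):
        samples = np.random.default_rng(0).standard_normal(4000)
        assert exceedance_prob(samples) == pytest.approx(0.5, abs=0.05)

    def test_five_sigma_tail(self):
        assert exceedance_prob(5.0, 1.0) < 0.001

    def test_bootstrap_vs_wald_agreement(self):
        rng = np.random.default_rng(1)
        est, se = 1.2, 1.0
        samples = rng.normal(est, se, 20000)
        assert exceedance_prob(samples) == pytest.approx(exceedance_prob(est, se), abs=0.02)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            exceedance_prob(np.ones(10))
        with pytest.raises(ValueError, match="degenerate"):
            exceedance_prob(1.0, 0.0)


class TestRateModel:
    def test_identical_groups_near_zero_effect(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(340, 19)
        rows = []
        for g in ("patient", "control"):
            for i, c in enumerate(counts):
                rows.append(
                    {"subject": f"{g}{i}", "group": g, "session": 1,
                     "n_bursts": c, "analyzed_s": 180.0, "rate_per_min": c / 3.0}
                )
        df = pd.DataFrame(rows)
        res = fit_rate_model(df)
        assert abs(res.contrasts["group"]["pct"]) < 0.05
        assert res.bf_group < 1.0

    def test_study_scale_deficit_recovered(self):
        res = fit_rate_model(count_summaries(4))
        pct = res.contrasts["group"]["pct"]
        assert -20.0 < pct < -3.0  # around the reported 5-17% lower rate

    def test_single_group_no_contrast(self):
        df = count_summaries(5)
        res = fit_rate_model(df[df["group"] == "patient"])
        assert "group" not in res.contrasts
        assert res.bf_group is None

    def test_coverage_and_bias_of_group_contrast(self):
        """95% CI coverage and small bias across many simulated cohorts."""
        planted = -15.0
        pat_mean = 120.0 * (1 + planted / 100.0)
        hits, ests = 0, []
        n_sims = 100
        for seed in range(n_sims):
            res = fit_rate_model(count_summaries(seed + 1000, pat_mean=pat_mean))
            c = res.contrasts["group"]
            ests.append(c["pct"])
            if c["pct_ci_lo"] <= planted <= c["pct_ci_hi"]:
                hits += 1
        assert abs(np.mean(ests) - planted) < 2.0
        assert 0.90 <= hits / n_sims <= 0.99


class TestFeatureModel:
    @staticmethod
    def event_values(seed, n_sub=25, per_sub=40, group_ratio=1.0, sigma=0.35, mu=np.log(140.0)):
        rng = np.random.default_rng(seed)
        rows, values = [], []
        for g, ratio in [("patient", group_ratio), ("control", 1.0)]:
            for i in range(n_sub):
                subj_mu = mu + np.log(ratio) + rng.normal(0, 0.1)
                for sess in (1, 2):
                    vals = rng.lognormal(subj_mu, sigma, per_sub)
                    for v in vals:
                        rows.append({"subject": f"{g}{i}", "group": g, "session": sess})
                        values.append(v)
        return np.array(values), pd.DataFrame(rows)

    def test_null_difference_covered(self):
        values, design = self.event_values(0)
        res = fit_feature_model(values, design, family="lognormal")
        c = res.contrasts["group"]
        assert c["pct_ci_lo"] < 0.0 < c["pct_ci_hi"]

    def test_planted_ten_percent_difference_recovered(self):
        hits = 0
        for seed in range(10):
            values, design = self.event_values(seed, group_ratio=0.90)
            c = fit_feature_model(values, design, family="lognormal").contrasts["group"]
            if c["pct_ci_lo"] <= -10.0 <= c["pct_ci_hi"]:
                hits += 1
        assert hits >= 9

    def test_zero_shift_reduces_to_lognormal(self):
        values, design = self.event_values(1, n_sub=8, per_sub=15)
        ln = fit_feature_model(values, design, family="lognormal")
        shifted = fit_feature_model(values, design, family="shifted_lognormal",
                                    shift_grid_n=1)  # grid = {0}
        assert shifted.shift == 0.0
        np.testing.assert_allclose(
            ln.coefficients["estimate"], shifted.coefficients["estimate"], atol=1e-10
        )

    def test_nonpositive_after_shift_rejected(self):
        design = pd.DataFrame(
            {"subject": ["a", "a", "b", "b"], "group": ["patient"] * 4, "session": [1, 1, 2, 2]}
        )
        with pytest.raises(ValueError, match="no finite|non-positive"):
            fit_feature_model(np.array([np.nan, np.nan, np.nan, np.nan]), design)


class TestSymptomModels:
    @staticmethod
    def patient_table(seed, n=19):
        rng = np.random.default_rng(seed)
        rates = np.clip(rng.normal(106.0, 8.0, n), 0.0, None)
        df = pd.DataFrame(
            {
                "subject": np.repeat([f"p{i:02d}" for i in range(n)], 2),
                "session": np.tile([1, 2], n),
                "rate_per_min": np.repeat(rates, 2),
            }
        )
        return df

    def test_planted_bradykinesia_effect_recovered(self):
        spec = {"bradykinesia": SymptomGenSpec(np.log(13.0), -28.0, ref_rate=106.0)}
        covered = 0
        for seed in range(5):
            df = self.patient_table(seed)
            scores = gen_clinical_table(df, spec, seed + 50)
            eff = fit_symptom_models(df.assign(group="patient"), scores,
                                     factors=["bradykinesia"])[0]
            if eff.ci_lo <= -28.0 <= eff.ci_hi:
                covered += 1
        assert covered >= 4

    def test_score_doubling_leaves_slope_unchanged(self):
        spec = {"rigidity": SymptomGenSpec(np.log(6.0), -20.0, ref_rate=106.0)}
        df = self.patient_table(3)
        scores = gen_clinical_table(df, spec, 99)
        doubled = scores.copy()
        doubled["rigidity"] = 2 * doubled["rigidity"]
        e1 = fit_symptom_models(df.assign(group="patient"), scores, factors=["rigidity"])[0]
        e2 = fit_symptom_models(df.assign(group="patient"), doubled, factors=["rigidity"])[0]
        # exact invariance holds for the fixed-effects Poisson model; the
        # random intercept re-weights slightly, so allow a small wobble
        assert e2.pct_change_per_10 == pytest.approx(e1.pct_change_per_10, abs=3.0)

    def test_all_zero_factor_skipped_with_warning(self):
        df = self.patient_table(4)
        scores = df[["subject", "session"]].copy()
        scores["rest_tremor"] = 0
        with pytest.warns(RuntimeWarning, match="all-zero"):
            effects = fit_symptom_models(df.assign(group="patient"), scores,
                                         factors=["rest_tremor"])
        assert effects == []
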