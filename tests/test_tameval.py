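"""Survey battery: reliability closed forms, path/OR recovery, logistics."""

import numpy as np
import pytest

from epiedu import tameval as tv
from epiedu.errors import SeparationError, ValidationError


class TestResponseRate:
    def test_study_arithmetic(self):
        assert tv.response_rate(305, 327) == 93.3

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValidationError):
            tv.response_rate(10, 5)


class TestCronbachAlpha:
    def test_perfectly_correlated_items(self):
        x = np.tile(np.array([[1.0], [2.0], [3.0], [4.0]]), (1, 3))
        assert tv.cronbach_alpha(x) == pytest.approx(1.0)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((5000, 4))
        assert abs(tv.cronbach_alpha(x)) < 0.1

    def test_hand_computed_matrix(self):
        x = np.array([[1.0, 2.0, 3.0],
                      [2.0, 3.0, 3.0],
                      [3.0, 5.0, 4.0],
                      [4.0, 6.0, 6.0]])
        # manual: item vars (ddof=1) = 5/3, 10/3, 2 ; total scores
        # (6, 8, 12, 16), var = 59/3 ; alpha = (3/2)(1 - 7/(59/3))
        manual = 1.5 * (1 - (5 / 3 + 10 / 3 + 2) / (59 / 3))
        assert tv.cronbach_alpha(x) == pytest.approx(manual)

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ValidationError):
            tv.cronbach_alpha(np.ones((4, 3)))


class TestAVE:
    def test_unit_loadings(self):
        assert tv.ave([1, 1, 1]) == 1.0

    def test_study_style_loadings(self):
        assert tv.ave([0.8, 0.8, 0.8]) == pytest.approx(0.64)

    def test_half(self):
        assert tv.ave([1, 0]) == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            tv.ave([])


class TestEhlSplit:
    def _resp(self, totals):
        out = []
        for i, t in enumerate(totals):
            r = tv.SurveyResponse(
                respondent_id=f"r{i}", age_years=30, age_band="18-30",
                gender="female", education="college",
                pu_items=[3], peou_items=[3], bi_items=[3],
                ehl_items=[t], ehl_group="", effectiveness=1,
                official_source_trust=1, preferred_format="text")
            out.append(r)
        return out

    def test_strict_median_split(self):
        resp = tv.ehl_split(self._resp([10, 20, 30]))
        assert [r.ehl_group for r in resp] == \
            ["medium_low", "medium_low", "high"]

    def test_all_ties_fall_low(self):
        resp = tv.ehl_split(self._resp([20, 20, 20]))
        assert {r.ehl_group for r in resp} == {"medium_low"}

    def test_order_invariant(self):
        a = tv.ehl_split(self._resp([10, 30, 20, 40]))
        b = tv.ehl_split(self._resp([40, 20, 30, 10]))
        assert sorted((sum(r.ehl_items), r.ehl_group) for r in a) == \
            sorted((sum(r.ehl_items), r.ehl_group) for r in b)


def _null_config(seed, n=305, **kw):
    coefs = {p: 0.0 for p in tv.PATHS}
    return tv.SurveyConfig(n_respondents=n, path_coefs=coefs, seed=seed, **kw)


class TestSimulate:
    def test_deterministic_per_seed(self):
        a = tv.simulate_survey(tv.SurveyConfig(seed=5))
        b = tv.simulate_survey(tv.SurveyConfig(seed=5))
        assert tv.to_dataframe(a).equals(tv.to_dataframe(b))

    def test_null_model_composites_uncorrelated(self):
        resp = tv.simulate_survey(_null_config(seed=2, n=2000))
        df = tv.fit_paths(resp).composites
        se = 1 / np.sqrt(2000)
        for a, b in (("PU", "PEOU"), ("PU", "BI"), ("PEOU", "BI")):
            assert abs(np.corrcoef(df[a], df[b])[0, 1]) < 3 * se

    def test_likert_items_in_range(self):
        resp = tv.simulate_survey(tv.SurveyConfig(n_respondents=50, seed=3))
        for r in resp:
            for items in (r.pu_items, r.peou_items, r.bi_items, r.ehl_items):
                assert all(1 <= v <= 5 for v in items)

    def test_dataframe_round_trip(self):
        resp = tv.simulate_survey(tv.SurveyConfig(n_respondents=20, seed=4))
        back = tv.from_dataframe(tv.to_dataframe(resp))
        assert tv.to_dataframe(back).equals(tv.to_dataframe(resp))


class TestPathFitting:
    def test_planted_paths_recovered_over_replicates(self):
        ests = {p: [] for p in tv.PATHS}
        for rep in range(20):
            cfg = tv.SurveyConfig(n_respondents=305, loading=1.0,
                                  discretize=False, seed=3000 + rep)
            res = tv.fit_paths(tv.simulate_survey(cfg))
            for p in tv.PATHS:
                ests[p].append(res.betas[p])
        for p, target in tv.DEFAULT_PATH_COEFS.items():
            mean = np.mean(ests[p])
            se = np.std(ests[p], ddof=1) / np.sqrt(len(ests[p]))
            assert abs(mean - target) < 3 * se, (p, mean, target)

    def test_order_invariant(self):
        resp = tv.simulate_survey(tv.SurveyConfig(n_respondents=80, seed=6))
        a = tv.fit_paths(resp).betas
        b = tv.fit_paths(list(reversed(resp))).betas
        for p in tv.PATHS:
            assert a[p] == pytest.approx(b[p])

    def test_too_few_respondents_rejected(self):
        resp = tv.simulate_survey(tv.SurveyConfig(n_respondents=10, seed=7))
        with pytest.raises(ValidationError):
            tv.fit_paths(resp)


class TestModeration:
    def test_null_interactions_and_nonnegative_delta_r2(self):
        resp = tv.simulate_survey(_null_config(seed=8, n=2000,
                                               loading=1.0, discretize=False))
        mod = tv.moderation_hierarchy(resp)
        se = 2 / np.sqrt(2000)
        assert abs(mod.step2_betas["eHLxPU"]) < 3 * se
        assert abs(mod.step2_betas["eHLxPEOU"]) < 3 * se
        assert mod.delta_r2 >= 0
        assert mod.delta_r2 < 0.01

    def test_planted_interaction_recovered(self):
        ests = []
        for rep in range(20):
            cfg = tv.SurveyConfig(n_respondents=305, loading=1.0,
                                  discretize=False, seed=4000 + rep)
            mod = tv.moderation_hierarchy(tv.simulate_survey(cfg))
            ests.append(mod.step2_betas["eHLxPEOU"])
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - 0.22) < 3 * se
        assert all(tv.moderation_hierarchy(
            tv.simulate_survey(tv.SurveyConfig(n_respondents=100,
                                               seed=s))).delta_r2 >= 0
                   for s in range(3))


class TestLogit:
    def test_planted_or_recovered_at_large_n(self):
        ors = {"age60plus": 2.0, "college_edu": 1.0, "high_ehl": 1.0,
               "official_source": 1.0}
        cfg = tv.SurveyConfig(n_respondents=10000, logit_odds_ratios=ors,
                              seed=9)
        res = tv.logit_effectiveness(tv.simulate_survey(cfg))
        assert 1.8 < res.odds_ratio["age60plus"] < 2.2

    def test_null_covariate_or_near_one(self):
        ors = {v: 1.0 for v in tv.LOGIT_VARS}
        cfg = tv.SurveyConfig(n_respondents=10000, logit_odds_ratios=ors,
                              seed=10)
        res = tv.logit_effectiveness(tv.simulate_survey(cfg))
        for v in tv.LOGIT_VARS:
            assert 0.85 < res.odds_ratio[v] < 1.18

    def test_constant_outcome_raises_separation(self):
        resp = tv.simulate_survey(tv.SurveyConfig(n_respondents=50, seed=11))
        for r in resp:
            r.effectiveness = 1
        with pytest.raises(SeparationError):
            tv.logit_effectiveness(resp)

    def test_separating_variable_named(self):
        resp = tv.simulate_survey(tv.SurveyConfig(n_respondents=200, seed=12))
        for r in resp:
            r.effectiveness = 1 if r.official_source_trust else 0
        with pytest.raises(SeparationError, match="official_source"):
            tv.logit_effectiveness(resp)

    def test_or_equals_exp_coef_exactly(self):
        resp = tv.simulate_survey(tv.SurveyConfig(n_respondents=500, seed=13))
        res = tv.logit_effectiveness(resp)
        for v, c in res.coef.items():
            assert res.odds_ratio[v] == pytest.approx(np.exp(c), abs=1e-12)

    def test_loglik_nondecreasing_over_irls(self):
        resp = tv.simulate_survey(tv.SurveyConfig(n_respondents=500, seed=14))
        res = tv.logit_effectiveness(resp)
        trace = res.loglik_trace
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_matches_statsmodels_mle(self):
        import statsmodels.api as sm

        resp = tv.simulate_survey(tv.SurveyConfig(n_respondents=800, seed=15))
        res = tv.logit_effectiveness(resp)
        y = np.array([r.effectiveness for r in resp], dtype=float)
        X = np.column_stack([
            np.ones(len(resp)),
            [1.0 if r.age_band == "60+" else 0.0 for r in resp],
            [1.0 if r.education in ("college", "postgraduate") else 0.0
             for r in resp],
            [1.0 if r.ehl_group == "high" else 0.0 for r in resp],
            [float(r.official_source_trust) for r in resp],
        ])
        ref = sm.Logit(y, X).fit(disp=0)
        ours = [res.coef[k] for k in ("const",) + tv.LOGIT_VARS]
        assert np.allclose(ours, ref.params, atol=1e-6)
        refse = [res.se[k] for k in ("const",) + tv.LOGIT_VARS]
        assert np.allclose(refse, ref.bse, atol=1e-5)


class TestFormatChi2:
    def test_age_preference_association_detected(self):
        resp = tv.simulate_survey(tv.SurveyConfig(n_respondents=305, seed=16))
        res = tv.format_preference_chi2(resp)
        assert res.p_value < 0.001
        assert res.expected.sum() == pytest.approx(305)

    def test_independent_preferences_small_statistic(self):
        resp = tv.simulate_survey(tv.SurveyConfig(n_respondents=400, seed=17))
        rng = np.random.default_rng(0)
        for r in resp:
            r.preferred_format = str(rng.choice(tv.FORMATS))
        res = tv.format_preference_chi2(resp)
        assert res.p_value > 0.01


class TestReliabilityReport:
    def test_default_design_meets_thresholds(self):
        resp = tv.simulate_survey(tv.SurveyConfig(n_respondents=305, seed=18))
        rel = tv.reliability_report(resp)
        for c in ("PU", "PEOU", "BI", "eHL"):
            assert rel.cronbach_alpha[c] > 0.8
            assert rel.ave[c] > 0.5
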