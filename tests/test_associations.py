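"""Evaluation statistics against generating models and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from lpai.data import SurvivalTable
from lpai.associations import (
    change_paa,
    compute_paa,
    concordance_index,
    cox_hazard_ratio,
    fine_gray_hr,
    frailty_category,
    kaplan_meier_logrank,
    landmark_hazard_ratios,
    multimorbidity_index,
    ordinal_odds_ratio,
    poisson_rate_ratio,
    protein_mortality_screen,
    train_cross_sectional_pac,
)


def make_cohort(rng, n, log_hr=np.log(2.0), base=0.05, horizon=10.0,
                competing=0.0):
    subjects = [f"s{i}" for i in range(n)]
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    t = rng.exponential(np.exp(-log_hr * x) / base)
    event = (t <= horizon).astype(int)
    time = np.minimum(t, horizon)
    if competing > 0:
        cause = np.where(event == 1,
                         rng.choice(["cvd", "other"], n,
                                    p=[1 - competing, competing]), "none")
    else:
        cause = np.where(event == 1, "cvd", "none")
    surv = SurvivalTable(pd.DataFrame(
        {"subject_id": subjects, "time": time, "event": event, "cause": cause}
    ))
    return pd.Series(x, index=subjects), surv


class TestCoxHazardRatio:
    def test_recovers_generating_hr_with_coverage(self):
        inside, covered = 0, 0
        n_seeds = 20
        for s in range(n_seeds):
            rng = np.random.default_rng(300 + s)
            x, surv = make_cohort(rng, 2000)
            r = cox_hazard_ratio(x, surv)
            inside += 1.8 <= r.estimate <= 2.2
            covered += r.ci_low <= 2.0 <= r.ci_high
        assert inside >= 0.8 * n_seeds
        assert covered >= 0.9 * n_seeds

    def test_null_exposure_ci_covers_one(self):
        covered = 0
        n_seeds = 20
        for s in range(n_seeds):
            rng = np.random.default_rng(400 + s)
            x, surv = make_cohort(rng, 500)
            permuted = pd.Series(rng.permutation(x.to_numpy()), index=x.index)
            r = cox_hazard_ratio(permuted, surv)
            covered += r.ci_low <= 1.0 <= r.ci_high
        assert covered >= 0.9 * n_seeds

    def test_matches_brute_force_mle_with_covariates(self):
        rng = np.random.default_rng(7)
        x, surv = make_cohort(rng, 30, base=0.3)
        cov = pd.DataFrame({
            "subject_id": x.index,
            "age": rng.uniform(50, 80, 30),
            "bmi": rng.normal(28, 4, 30),
        })
        from lpai.data import CovariateTable

        r = cox_hazard_ratio(x, surv, CovariateTable(cov))
        df = surv.aligned(list(x.index))
        X = np.column_stack([cov["age"], cov["bmi"], x.to_numpy()])

        def negll(b):
            eta = X @ b
            out = 0.0
            t, e = df["time"].to_numpy(), df["event"].to_numpy()
            for i in np.flatnonzero(e):
                out -= eta[i] - np.log(np.exp(eta[t >= t[i]]).sum())
            return out

        res = minimize(negll, np.zeros(3), method="BFGS",
                       options={"gtol": 1e-10})
        assert np.log(r.estimate) == pytest.approx(res.x[2], abs=1e-4)

    def test_log_hr_bias_shrinks_with_sample_size(self):
        biases = []
        for n in (500, 2000, 8000):
            errs = []
            for s in range(10):
                rng = np.random.default_rng(10_000 * n + s)
                x, surv = make_cohort(rng, n)
                r = cox_hazard_ratio(x, surv)
                errs.append(np.log(r.estimate) - np.log(2.0))
            biases.append(abs(float(np.median(errs))))
        assert biases[2] <= biases[0] + 0.01


class TestFineGray:
    def test_matches_frozen_cmprsk_oracle(self):
        """Deterministic fixture; expected log subdistribution HR frozen
        from R cmprsk::crr (coef 0.649768, se 0.123536)."""
        rng = np.random.default_rng(1234)
        n = 150
        x = rng.normal(size=n)
        t1 = rng.exponential(np.exp(-0.8 * x) / 0.15)
        t2 = rng.exponential(1 / 0.10, n)
        c = rng.uniform(2, 12, n)
        t = np.minimum(np.minimum(t1, t2), c)
        status = np.where(t == c, 0, np.where(t1 <= t2, 1, 2))
        subjects = [f"s{i}" for i in range(n)]
        surv = SurvivalTable(pd.DataFrame({
            "subject_id": subjects, "time": t,
            "event": (status > 0).astype(int),
            "cause": np.where(status == 1, "cvd",
                              np.where(status == 2, "other", "none")),
        }))
        r = fine_gray_hr(pd.Series(x, index=subjects), surv,
                         cause_of_interest="cvd")
        assert np.log(r.estimate) == pytest.approx(0.649768, abs=1e-4)

    def test_no_competing_events_equals_cause_specific_cox(self):
        rng = np.random.default_rng(2)
        x, surv = make_cohort(rng, 300)
        fg = fine_gray_hr(x, surv, cause_of_interest="cvd")
        cx = cox_hazard_ratio(x, surv)
        assert np.log(fg.estimate) == pytest.approx(np.log(cx.estimate),
                                                    abs=1e-6)

    def test_all_competing_is_error(self):
        rng = np.random.default_rng(3)
        x, surv = make_cohort(rng, 100)
        with pytest.raises(ValueError, match="no events of cause"):
            fine_gray_hr(x, surv, cause_of_interest="cancer")

    def test_recovers_subdistribution_effect(self):
        """Generator follows the subdistribution model exactly:
        F1(t|x) = 1 - (1 - F10(t))^exp(beta x) with a plateau baseline,
        so the per-SD subdistribution HR is exp(beta) = 1.8."""
        beta, p0, rate = np.log(1.8), 0.4, 0.3
        ests = []
        for s in range(5):
            rng = np.random.default_rng(600 + s)
            n = 1500
            subjects = [f"s{i}" for i in range(n)]
            x = rng.normal(size=n)
            x = (x - x.mean()) / x.std(ddof=1)
            e_bx = np.exp(beta * x)
            p1 = 1.0 - (1.0 - p0) ** e_bx
            is1 = rng.uniform(size=n) < p1
            u = rng.uniform(size=n)
            f10 = 1.0 - (1.0 - u * p1) ** (1.0 / e_bx)
            t1 = -np.log(1.0 - np.clip(f10 / p0, 0, 1 - 1e-12)) / rate
            time = np.where(is1, t1, rng.exponential(1 / 0.25, n))
            cens = rng.uniform(5, 20, n)
            event = (time <= cens).astype(int)
            cause = np.where(event == 0, "none",
                             np.where(is1, "cvd", "other"))
            surv = SurvivalTable(pd.DataFrame(
                {"subject_id": subjects, "time": np.minimum(time, cens),
                 "event": event, "cause": cause}))
            r = fine_gray_hr(pd.Series(x, index=subjects), surv,
                             cause_of_interest="cvd")
            ests.append(r.estimate)
        assert 1.6 <= float(np.median(ests)) <= 2.0


class TestKaplanMeierLogrank:
    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(4)
        n = 60
        subjects = [f"s{i}" for i in range(n)]
        time = rng.exponential(1.0, n)
        surv = SurvivalTable(pd.DataFrame(
            {"subject_id": subjects, "time": time, "event": 1,
             "cause": "cvd"}))
        groups = pd.Series(["low"] * 30 + ["high"] * 30, index=subjects)
        curves, _, _ = kaplan_meier_logrank(groups, surv)
        low = curves["low"].set_index("timeline")["low"]
        times_low = np.sort(time[:30])
        for t, s in low.items():
            if t > 0:
                assert s == pytest.approx((times_low > t).mean(), abs=1e-12)

    def test_product_limit_arithmetic_six_events(self):
        subjects = [f"s{i}" for i in range(6)]
        surv = SurvivalTable(pd.DataFrame(
            {"subject_id": subjects, "time": [1, 2, 3, 4, 5, 6.0],
             "event": 1, "cause": "cvd"}))
        groups = pd.Series(["a"] * 6, index=subjects)
        with pytest.raises(ValueError):
            kaplan_meier_logrank(groups, surv)  # a single group: no contrast
        groups = pd.Series(["a"] * 6 + ["b"] * 6,
                           index=subjects + [f"t{i}" for i in range(6)])
        surv2 = SurvivalTable(pd.DataFrame(
            {"subject_id": groups.index,
             "time": [1, 2, 3, 4, 5, 6.0] * 2, "event": 1, "cause": "cvd"}))
        curves, _, _ = kaplan_meier_logrank(groups, surv2)
        a = curves["a"].set_index("timeline")["a"]
        assert a.loc[3.0] == pytest.approx(0.5)

    def test_null_logrank_p_uniform(self):
        """Under identical hazards, log-rank p-values are uniform."""
        from scipy import stats

        pvals = []
        for s in range(200):
            rng = np.random.default_rng(5000 + s)
            n = 80
            subjects = [f"s{i}" for i in range(n)]
            time = rng.exponential(1.0, n)
            cens = rng.exponential(2.0, n)
            event = (time <= cens).astype(int)
            surv = SurvivalTable(pd.DataFrame(
                {"subject_id": subjects, "time": np.minimum(time, cens),
                 "event": event,
                 "cause": np.where(event == 1, "cvd", "none")}))
            groups = pd.Series(rng.permutation(["low"] * 40 + ["high"] * 40),
                               index=subjects)
            try:
                _, _, p = kaplan_meier_logrank(groups, surv)
            except ValueError:
                continue
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestPoisson:
    def test_recovers_rate_ratio(self):
        ests = []
        for s in range(20):
            rng = np.random.default_rng(700 + s)
            n = 2000
            subjects = [f"s{i}" for i in range(n)]
            x = rng.normal(size=n)
            x = (x - x.mean()) / x.std(ddof=1)
            counts = pd.Series(rng.poisson(np.exp(0.3 * x)), index=subjects)
            r = poisson_rate_ratio(pd.Series(x, index=subjects), counts)
            ests.append(r.estimate)
        assert 1.25 <= float(np.median(ests)) <= 1.45

    def test_null_ci_covers_one(self):
        rng = np.random.default_rng(8)
        n = 1000
        subjects = [f"s{i}" for i in range(n)]
        x = pd.Series(rng.normal(size=n), index=subjects)
        counts = pd.Series(rng.poisson(1.5, n), index=subjects)
        r = poisson_rate_ratio(x, counts)
        assert r.ci_low <= 1.0 <= r.ci_high

    def test_matches_direct_irls_oracle(self):
        rng = np.random.default_rng(9)
        n = 25
        subjects = [f"s{i}" for i in range(n)]
        x = rng.normal(size=n)
        counts = rng.poisson(np.exp(0.4 * x))
        r = poisson_rate_ratio(pd.Series(x, index=subjects),
                               pd.Series(counts, index=subjects))
        # independent IRLS implementation
        X = np.column_stack([np.ones(n), x])
        beta = np.zeros(2)
        for _ in range(50):
            mu = np.exp(X @ beta)
            W = mu
            z = X @ beta + (counts - mu) / mu
            beta_new = np.linalg.solve(X.T @ (W[:, None] * X),
                                       X.T @ (W * z))
            if np.abs(beta_new - beta).max() < 1e-12:
                beta = beta_new
                break
            beta = beta_new
        assert np.log(r.estimate) == pytest.approx(beta[1], abs=1e-6)

    def test_non_integer_counts_rejected(self):
        x = pd.Series([0.1, 0.2], index=["a", "b"])
        with pytest.raises(ValueError, match="integers"):
            poisson_rate_ratio(x, pd.Series([1.5, 2.0], index=["a", "b"]))


class TestOrdinal:
    ORDER = ["robust", "prefrail", "frail"]

    def _gen(self, rng, n, slope=0.4):
        subjects = [f"s{i}" for i in range(n)]
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std(ddof=1)
        lin = slope * x
        u = rng.uniform(size=n)
        p_r = 1 / (1 + np.exp(-(-0.2 - lin)))
        p_pf = 1 / (1 + np.exp(-(2.2 - lin)))
        cats = np.where(u < p_r, "robust",
                        np.where(u < p_pf, "prefrail", "frail"))
        return pd.Series(x, index=subjects), pd.Series(cats, index=subjects)

    def test_recovers_cumulative_odds_ratio(self):
        ests = []
        for s in range(20):
            rng = np.random.default_rng(800 + s)
            x, cats = self._gen(rng, 2000, slope=np.log(1.5))
            r = ordinal_odds_ratio(x, cats, order=self.ORDER)
            ests.append(r.estimate)
        assert 1.35 <= float(np.median(ests)) <= 1.65

    def test_two_categories_equals_binary_logistic(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(10)
        n = 300
        subjects = [f"s{i}" for i in range(n)]
        x = rng.normal(size=n)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-0.5 * x))).astype(int)
        cats = pd.Series(np.where(y == 1, "prefrail", "robust"),
                         index=subjects)
        r = ordinal_odds_ratio(pd.Series(x, index=subjects), cats,
                               order=["robust", "prefrail"])
        logit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert np.log(r.estimate) == pytest.approx(logit.params[1], abs=1e-5)

    def test_reversed_order_negates_coefficient(self):
        rng = np.random.default_rng(11)
        x, cats = self._gen(rng, 600)
        fwd = ordinal_odds_ratio(x, cats, order=self.ORDER)
        rev = ordinal_odds_ratio(x, cats, order=self.ORDER[::-1])
        assert np.log(fwd.estimate) == pytest.approx(-np.log(rev.estimate),
                                                     abs=1e-4)

    def test_sparse_category_rejected(self):
        rng = np.random.default_rng(12)
        x, cats = self._gen(rng, 40)
        cats[:] = "robust"
        cats.iloc[0] = "frail"
        with pytest.raises(ValueError, match="fewer than 3"):
            ordinal_odds_ratio(x, cats, order=self.ORDER)


class TestConcordance:
    def test_perfect_risk_ordering(self):
        rng = np.random.default_rng(13)
        n = 40
        subjects = [f"s{i}" for i in range(n)]
        time = np.sort(rng.exponential(1.0, n))
        surv = SurvivalTable(pd.DataFrame(
            {"subject_id": subjects, "time": time, "event": 1,
             "cause": "cvd"}))
        risk = pd.Series(-time, index=subjects)
        assert concordance_index(risk, surv) == 1.0

    def test_random_risk_near_half(self):
        cs = []
        for s in range(50):
            rng = np.random.default_rng(900 + s)
            x, surv = make_cohort(rng, 100, log_hr=0.0)
            cs.append(concordance_index(x, surv))
        assert abs(float(np.mean(cs)) - 0.5) < 0.02

    def test_equals_exhaustive_pair_enumeration(self):
        rng = np.random.default_rng(14)
        x, surv = make_cohort(rng, 50, base=0.15)
        c = concordance_index(x, surv)
        df = surv.aligned(list(x.index))
        time, event = df["time"].to_numpy(), df["event"].to_numpy()
        risk = x.to_numpy()
        num = den = 0.0
        for i in range(50):
            for j in range(50):
                if i == j or not event[i] or time[i] >= time[j]:
                    continue  # usable pairs: i fails first
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
        assert c == pytest.approx(num / den, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(15)
        x, surv = make_cohort(rng, 120)
        assert concordance_index(x, surv) == pytest.approx(
            concordance_index(np.exp(3 * x.to_numpy()) + 2, surv), abs=1e-12
        )


class TestLandmark:
    def test_landmark_zero_equals_plain_cox(self):
        rng = np.random.default_rng(16)
        x, surv = make_cohort(rng, 300)
        lm = landmark_hazard_ratios(x, surv, landmarks=[0])
        direct = cox_hazard_ratio(x, surv)
        assert lm[0].estimate == direct.estimate

    def test_early_events_excluded(self):
        rng = np.random.default_rng(17)
        x, surv = make_cohort(rng, 400)
        lm = landmark_hazard_ratios(x, surv, landmarks=[3.0])
        expected_n = int((surv.table["time"] > 3.0).sum())
        assert lm[3.0].n == expected_n

    def test_constant_effect_stable_across_landmarks(self):
        rng = np.random.default_rng(18)
        x, surv = make_cohort(rng, 3000)
        lm = landmark_hazard_ratios(x, surv, landmarks=[1.0, 3.0, 5.0])
        hrs = [r.estimate for r in lm.values()]
        assert max(hrs) / min(hrs) < 1.2


class TestProteinScreen:
    def _screen_inputs(self, rng, n=800, p=60, n_info=10, effect=0.5):
        subjects = [f"s{i}" for i in range(n)]
        X = rng.normal(size=(n, p))
        eta = X[:, :n_info] @ np.full(n_info, effect / np.sqrt(n_info))
        t = rng.exponential(np.exp(-eta) / 0.08)
        event = (t <= 10).astype(int)
        surv = SurvivalTable(pd.DataFrame(
            {"subject_id": subjects, "time": np.minimum(t, 10),
             "event": event, "cause": np.where(event == 1, "cvd", "none")}))
        values = pd.DataFrame(X, index=subjects,
                              columns=[f"p{j}" for j in range(p)])
        adjust = pd.DataFrame({"age": rng.uniform(50, 80, n),
                               "sex": rng.binomial(1, 0.5, n).astype(float)},
                              index=subjects)
        return values, surv, adjust

    def test_informative_proteins_flagged_nulls_controlled(self):
        tps, fps = [], []
        for s in range(3):
            rng = np.random.default_rng(1100 + s)
            values, surv, adjust = self._screen_inputs(rng, effect=1.2)
            out = protein_mortality_screen(values, surv, adjust)
            flagged = set(out.loc[out["significant"], "protein_id"])
            tps.append(len(flagged & {f"p{j}" for j in range(10)}))
            fps.append(len(flagged - {f"p{j}" for j in range(10)}) / 50)
        assert np.median(tps) >= 8
        assert np.median(fps) <= 0.05 + 0.04

    def test_all_null_panel_fdr_controlled(self):
        fracs = []
        for s in range(5):
            rng = np.random.default_rng(1200 + s)
            values, surv, adjust = self._screen_inputs(rng, n=400, p=40,
                                                       n_info=0, effect=0.0)
            out = protein_mortality_screen(values, surv, adjust)
            fracs.append(out["significant"].mean())
        assert float(np.mean(fracs)) <= 0.05

    def test_single_protein_reduces_to_raw_p(self):
        rng = np.random.default_rng(19)
        values, surv, adjust = self._screen_inputs(rng, n=200, p=1,
                                                   n_info=1, effect=0.8)
        out = protein_mortality_screen(values, surv, adjust)
        assert out["q"].iloc[0] == pytest.approx(out["p"].iloc[0])
        assert bool(out["significant"].iloc[0]) == (out["p"].iloc[0] <= 0.05)


class TestPacPaa:
    def test_noiseless_linear_age_signal(self):
        rng = np.random.default_rng(20)
        n, p = 300, 20
        X = rng.normal(size=(n, p))
        age = 60 + X[:, :5] @ np.array([3.0, -2.0, 1.5, 1.0, -1.0])
        subjects = [f"s{i}" for i in range(n)]
        values = pd.DataFrame(X, index=subjects,
                              columns=[f"p{j}" for j in range(p)])
        ages = pd.Series(age, index=subjects)
        pac = train_cross_sectional_pac(values.iloc[:200], ages.iloc[:200],
                                        random_state=0)
        pred = pac.predict(values.iloc[200:])
        resid = pred - ages.iloc[200:]
        r2 = 1 - resid.var() / ages.iloc[200:].var()
        assert r2 >= 0.99

    def test_zero_coefficients_predict_intercept(self):
        from lpai.associations import PacModel

        pac = PacModel(proteins=["p0"], coef=np.zeros(1), intercept=63.0,
                       alpha=0.5, training_subjects=[])
        values = pd.DataFrame({"p0": [1.0, -2.0]}, index=["a", "b"])
        assert (pac.predict(values) == 63.0).all()

    def test_same_seed_identical_coefficients(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(120, 10))
        age = 60 + X[:, 0] * 2 + rng.normal(0, 1, 120)
        subjects = [f"s{i}" for i in range(120)]
        values = pd.DataFrame(X, index=subjects)
        ages = pd.Series(age, index=subjects)
        a = train_cross_sectional_pac(values, ages, random_state=5)
        b = train_cross_sectional_pac(values, ages, random_state=5)
        assert np.array_equal(a.coef, b.coef)

    def test_paa_perfect_fit_is_zero(self):
        chron = pd.Series([50.0, 60.0, 70.0], index=["a", "b", "c"])
        pred = 2.0 + 1.0 * chron
        paa = compute_paa(pred, chron)
        assert np.allclose(paa, 0.0, atol=1e-10)

    def test_paa_residual_mean_zero(self):
        rng = np.random.default_rng(22)
        subjects = [f"s{i}" for i in range(100)]
        chron = pd.Series(rng.uniform(50, 80, 100), index=subjects)
        pred = chron * 0.8 + rng.normal(0, 3, 100)
        paa = compute_paa(pred, chron)
        assert paa.mean() == pytest.approx(0.0, abs=1e-10)

    def test_planted_acceleration_recovered(self):
        rng = np.random.default_rng(23)
        n = 400
        subjects = [f"s{i}" for i in range(n)]
        chron = pd.Series(rng.uniform(50, 80, n), index=subjects)
        accelerated = np.zeros(n, bool)
        accelerated[:80] = True
        pred = chron + np.where(accelerated, 5.0, 0.0) + rng.normal(0, 1, n)
        paa = compute_paa(pred, chron)
        gap = paa[accelerated].mean() - paa[~accelerated].mean()
        assert 4.0 <= gap <= 6.0

    def test_change_paa_subtraction(self):
        late = pd.Series([1.0, 2.0], index=["a", "b"])
        mid = pd.Series([0.5, -1.0], index=["a", "b"])
        assert (change_paa(late, mid) == pd.Series([0.5, 3.0],
                                                   index=["a", "b"])).all()

    def test_constant_chronological_age_rejected(self):
        chron = pd.Series([60.0, 60.0], index=["a", "b"])
        with pytest.raises(ValueError, match="constant"):
            compute_paa(pd.Series([61.0, 62.0], index=["a", "b"]), chron)


class TestMultimorbidityFrailty:
    @pytest.mark.parametrize("conditions,expected", [
        ({"mi": 1, "stroke": 1}, 3),
        ({}, 0),
        ({"diabetes": 1, "cancer": 1, "hf": 1}, 4),
        ({"mi": 1, "pvd": 1, "hf": 1, "copd": 1, "ckd": 1, "diabetes": 1,
          "dementia": 1, "stroke": 1, "cancer": 1}, 11),
    ])
    def test_weighted_counts(self, conditions, expected):
        assert multimorbidity_index(conditions) == expected

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="unknown condition"):
            multimorbidity_index({"gout": 1})

    @pytest.mark.parametrize("count,complete,expected", [
        (3, True, "frail"), (5, True, "frail"), (2, True, "prefrail"),
        (1, False, "prefrail"), (0, True, "robust"), (0, False, None),
    ])
    def test_frailty_phenotype_coding(self, count, complete, expected):
        assert frailty_category(count, complete) == expected

    def test_out_of_range_component_count(self):
        with pytest.raises(ValueError):
            frailty_category(6)
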