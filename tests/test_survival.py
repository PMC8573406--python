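import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from pathmir import (
    ExpressionMatrix,
    SurvivalTable,
    assign_groups,
    clinical_utility,
    correlate_markers,
    km_logrank,
    lasso_cox_loocv,
    multivariable_cox,
    optimal_cutoff,
    performance_metrics,
    select_candidates,
    signature_score,
    stratify_two_markers,
    univariate_cox,
)
from pathmir.survival import (
    CoxFit,
    SignatureModel,
    TermFit,
    _cox_log_partial_likelihood,
    default_lambda_grid,
    lambda_max,
)


def _surv(time, event, ids=None):
    ids = ids or [f"p{i}" for i in range(len(time))]
    return SurvivalTable(pd.DataFrame({"time": time, "event": event}, index=ids))


def _exp_cohort(rng, n, log_hr, censor=0.0):
    x = rng.normal(size=n)
    t = rng.exponential(1.0 / (0.1 * np.exp(log_hr * x)))
    e = np.ones(n, int)
    if censor > 0:
        c = rng.exponential(np.quantile(t, 1 - censor) * 2, n)
        e = (t <= c).astype(int)
        t = np.minimum(t, c)
    ids = [f"p{i}" for i in range(n)]
    return pd.Series(x, index=ids), _surv(t, e, ids)


class TestUnivariateCox:
    def test_negation_flips_coefficient(self, rng):
        x, surv = _exp_cohort(rng, 80, 0.6)
        a = univariate_cox(x, surv, "f")["f"].coefficient
        b = univariate_cox(-x, surv, "f")["f"].coefficient
        assert a == pytest.approx(-b, abs=1e-8)

    def test_planted_log_hr_recovered(self, rng):
        x, surv = _exp_cohort(rng, 300, 0.5, censor=0.3)
        fit = univariate_cox(x, surv, "f")
        term = fit["f"]
        se = (np.log(term.ci_high) - np.log(term.ci_low)) / (2 * 1.96)
        assert abs(term.coefficient - 0.5) < 3 * se

    def test_hr_matches_exp_coefficient(self, rng):
        x, surv = _exp_cohort(rng, 60, 0.4)
        term = univariate_cox(x, surv, "f")["f"]
        assert term.hr == pytest.approx(np.exp(term.coefficient))
        assert term.ci_low <= term.hr <= term.ci_high


class TestSelectCandidates:
    def _fit(self, coef, p):
        return CoxFit({"x": TermFit(coef, float(np.exp(coef)), 0.1, 10.0, p)},
                      converged=True, n=50, n_events=30)

    def test_screen_rules(self):
        fits = {
            "A": {"m1": self._fit(0.3, 0.05), "m2": self._fit(0.3, 0.05),
                  "m3": self._fit(0.3, 0.05)},
            "B": {"m1": self._fit(0.2, 0.2),   # fails p in B
                  "m2": self._fit(-0.4, 0.08),  # discordant direction
                  "m3": self._fit(0.2, 0.08)},  # concordant, both p < 0.1
        }
        assert select_candidates(fits) == ["m3"]

    def test_any_mode_is_looser(self):
        fits = {
            "A": {"m1": self._fit(0.3, 0.05)},
            "B": {"m1": self._fit(0.2, 0.5)},
        }
        assert select_candidates(fits, mode="any") == ["m1"]
        assert select_candidates(fits, mode="all") == []


class TestLassoCox:
    def _design(self, rng, n=120, p=6, betas=(0.8, -0.8)):
        X = rng.normal(size=(n, p))
        eta = X[:, 0] * betas[0] + X[:, 1] * betas[1]
        t = rng.exponential(1.0 / (0.05 * np.exp(eta)))
        ids = [f"p{i}" for i in range(n)]
        em = ExpressionMatrix(
            pd.DataFrame(X.T, index=[f"f{j}" for j in range(p)], columns=ids), "zscore")
        return em, _surv(t, np.ones(n, int), ids), X, t

    def test_lambda_max_empties_model(self, rng):
        em, surv, X, t = self._design(rng)
        lmax = lambda_max(X, t.astype(float) if hasattr(t, "astype") else t,
                          np.ones(len(t), int))
        with pytest.raises(ValueError, match="signature empty"):
            lasso_cox_loocv(em, surv, lambda_grid=[lmax * 2.0, lmax * 1.5])

    def test_small_lambda_matches_unpenalized(self, rng):
        em, surv, X, t = self._design(rng, n=80, p=3, betas=(0.5, -0.3))
        from pathmir.survival import _coxnet_path
        from sksurv.util import Surv

        y = Surv.from_arrays(event=np.ones(len(t), bool), time=t)
        co = _coxnet_path(X, y, np.geomspace(0.1, 1e-7, 60))[:, -1]
        from lifelines import CoxPHFitter

        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["time"], df["event"] = t, 1
        cph = CoxPHFitter().fit(df, "time", "event")
        assert np.abs(co - cph.params_.to_numpy()).max() < 1e-4

    def test_planted_features_selected_with_signs(self, rng):
        em, surv, X, t = self._design(rng, n=150, p=8)
        model, table = lasso_cox_loocv(em, surv)
        coef = dict(zip(model.mirna_ids, model.coefficients))
        assert coef.get("f0", 0) > 0 and coef.get("f1", 0) < 0
        assert table["mean_deviance"].idxmin() is not None

    def test_breslow_loglik_matches_direct_sum(self, rng):
        # independent O(n^2) evaluation of the Breslow partial likelihood
        n = 25
        X = rng.normal(size=(n, 2))
        t = rng.exponential(1, n)
        e = rng.integers(0, 2, n)
        e[0] = 1
        beta = np.array([0.4, -0.7])
        eta = X @ beta
        direct = sum(
            eta[i] - np.log(np.sum(np.exp(eta[t >= t[i]])))
            for i in range(n) if e[i] == 1
        )
        assert _cox_log_partial_likelihood(X, t, e, beta) == pytest.approx(direct, abs=1e-9)


class TestSignatureScore:
    def test_identity_and_hand_arithmetic(self):
        em = ExpressionMatrix(
            pd.DataFrame([[1.0, 2.0], [2.0, 0.5]], index=["ma", "mb"],
                         columns=["s1", "s2"]), "zscore")
        single = SignatureModel(["ma"], [1.0], 0.1)
        assert signature_score(em, single).tolist() == [1.0, 2.0]
        model = SignatureModel(["ma", "mb"], [0.3, -0.2], 0.1)
        # 0.3*1.0 + (-0.2)*2.0 = -0.1
        assert signature_score(em, model)["s1"] == pytest.approx(-0.1)

    def test_linearity(self, rng):
        em = ExpressionMatrix(
            pd.DataFrame(rng.normal(size=(3, 5)), index=["a", "b", "c"],
                         columns=[f"s{j}" for j in range(5)]), "zscore")
        m1 = SignatureModel(["a", "b", "c"], [0.5, -0.2, 0.1], 0.1)
        m2 = SignatureModel(["a", "b", "c"], [0.3, 0.4, -0.6], 0.1)
        msum = SignatureModel(["a", "b", "c"], [0.8, 0.2, -0.5], 0.1)
        total = signature_score(em, m1) + signature_score(em, m2)
        assert np.allclose(total, signature_score(em, msum))

    def test_missing_mirna_named(self):
        em = ExpressionMatrix(pd.DataFrame([[1.0, 2.0]], index=["ma"],
                                           columns=["s1", "s2"]), "zscore")
        with pytest.raises(KeyError, match="ghost"):
            signature_score(em, SignatureModel(["ghost"], [1.0], 0.1))


def exhaustive_cutoff_oracle(scores, surv, min_prop):
    best = (-np.inf, None)
    s = scores.loc[surv.sample_ids].to_numpy()
    n = len(s)
    for c in np.unique(s):
        high = s > c
        if high.sum() < min_prop * n or (n - high.sum()) < min_prop * n:
            continue
        stat = logrank_test(surv.time[high], surv.time[~high],
                            surv.event[high], surv.event[~high]).test_statistic
        if stat > best[0]:
            best = (stat, float(c))
    return best[1]


class TestOptimalCutoff:
    def test_separated_clusters(self, rng):
        low = rng.normal(0, 0.2, 25)
        high = rng.normal(5, 0.2, 25)
        scores = pd.Series(np.r_[low, high], index=[f"p{i}" for i in range(50)])
        t = np.r_[rng.exponential(50, 25), rng.exponential(5, 25)] + 0.01
        surv = _surv(t, np.ones(50, int))
        cut = optimal_cutoff(scores, surv)
        assert low.max() <= cut < high.min()

    def test_matches_exhaustive_oracle(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            n = int(r.integers(20, 60))
            scores = pd.Series(r.normal(size=n), index=[f"p{i}" for i in range(n)])
            surv = _surv(r.exponential(10, n) + 0.01, r.integers(0, 2, n) | 1)
            assert optimal_cutoff(scores, surv) == exhaustive_cutoff_oracle(scores, surv, 0.1)

    def test_needs_distinct_scores(self):
        scores = pd.Series([1.0, 1.0, 1.0], index=["a", "b", "c"])
        surv = _surv([1, 2, 3], [1, 1, 1], ids=["a", "b", "c"])
        with pytest.raises(ValueError):
            optimal_cutoff(scores, surv)


class TestKmLogrank:
    def test_product_limit_hand_example(self):
        # high group: events at t=1,2,4,6, censoring at 3 and 5; product-limit
        # gives S(1)=5/6, S(2)=4/6, S(4)=4/6*(2/3)=4/9, S(6)=0
        surv = _surv([1, 2, 3, 4, 5, 6, 9.0], [1, 1, 0, 1, 0, 1, 1],
                     ids=[f"p{i}" for i in range(7)])
        scores = pd.Series([9, 9, 9, 9, 9, 9, 1.0], index=surv.sample_ids)
        comp = km_logrank(assign_groups(scores, 5.0), surv)
        km_high = comp.km_curves["high"]["high"]
        for t, expected in [(1.0, 5 / 6), (2.0, 4 / 6), (4.0, 4 / 9), (6.0, 0.0)]:
            assert km_high.loc[t] == pytest.approx(expected, abs=1e-12)

    def test_km_curves_monotone(self, rng):
        n = 60
        scores = pd.Series(rng.normal(size=n), index=[f"p{i}" for i in range(n)])
        surv = _surv(rng.exponential(10, n) + 0.01, rng.integers(0, 2, n) | 1)
        comp = km_logrank(assign_groups(scores, 0.0), surv)
        for curve in comp.km_curves.values():
            vals = curve.iloc[:, 0].to_numpy()
            assert vals[0] == pytest.approx(1.0)
            assert np.all(np.diff(vals) <= 1e-12)

    def test_planted_group_hazard_recovered(self, rng):
        n = 150
        high = np.zeros(n, bool)
        high[: n // 2] = True
        t = np.where(high,
                     rng.exponential(1 / 0.3, n),
                     rng.exponential(1 / 0.1, n))
        surv = _surv(t, np.ones(n, int))
        scores = pd.Series(high.astype(float), index=surv.sample_ids)
        comp = km_logrank(assign_groups(scores, 0.5), surv)
        se = (np.log(comp.hr_ci[1]) - np.log(comp.hr_ci[0])) / (2 * 1.96)
        assert abs(np.log(comp.hr) - np.log(3.0)) < 3 * se

    def test_single_group_rejected(self, toy_survival):
        scores = pd.Series(np.ones(6), index=toy_survival.sample_ids)
        with pytest.raises(ValueError):
            km_logrank(assign_groups(scores, 0.0), toy_survival)


class TestMultivariableCox:
    def test_duplicate_covariate_is_collinear(self, rng):
        x, surv = _exp_cohort(rng, 60, 0.5)
        cov = pd.DataFrame({"copy": x}, index=x.index)
        with pytest.raises(ValueError, match="collinear"):
            multivariable_cox(x, cov, surv)

    def test_independent_covariate_leaves_hr(self, rng):
        x, surv = _exp_cohort(rng, 200, 0.5)
        cov = pd.DataFrame({"age": rng.normal(60, 8, 200)}, index=x.index)
        adj = multivariable_cox(x, cov, surv)["score"]
        unadj = univariate_cox(x, surv, "score")["score"]
        assert adj.coefficient == pytest.approx(unadj.coefficient, abs=0.1)


class TestPerformanceMetrics:
    def test_perfect_score_concordance(self):
        t = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        scores = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0],
                           index=[f"p{i}" for i in range(5)])
        surv = _surv(t, np.ones(5, int))
        perf = performance_metrics(scores, surv, times=[2.5])
        assert perf.c_index == pytest.approx(1.0)

    def test_random_score_near_half(self, rng):
        cs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 100
            scores = pd.Series(r.normal(size=n), index=[f"p{i}" for i in range(n)])
            surv = _surv(r.exponential(10, n) + 0.01, np.ones(n, int))
            cs.append(performance_metrics(scores, surv, times=[5.0]).c_index)
        assert abs(np.mean(cs) - 0.5) < 0.05

    def test_auc_matches_counting_oracle(self, rng):
        n = 10
        t = rng.exponential(10, n) + 0.01
        scores = pd.Series(rng.normal(size=n), index=[f"p{i}" for i in range(n)])
        surv = _surv(t, np.ones(n, int))
        horizon = float(np.median(t))
        perf = performance_metrics(scores, surv, times=[horizon])
        cases = t <= horizon
        controls = ~cases
        s = scores.to_numpy()
        pairs = [(i, j) for i in range(n) for j in range(n) if cases[i] and controls[j]]
        oracle = np.mean([1.0 if s[i] > s[j] else 0.5 if s[i] == s[j] else 0.0
                          for i, j in pairs])
        assert perf.auc_at_times[horizon] == pytest.approx(oracle, abs=1e-8)

    def test_c_degrades_with_noise(self, rng):
        n = 200
        eta = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.1 * np.exp(eta)))
        surv = _surv(t, np.ones(n, int))
        ids = surv.sample_ids
        cs = []
        for noise in (0.0, 1.0, 3.0):
            s = pd.Series(eta + noise * rng.normal(size=n), index=ids)
            cs.append(performance_metrics(s, surv, times=[5.0]).c_index)
        assert cs[0] > cs[1] > cs[2]


class TestClinicalUtility:
    def test_reference_curves(self, rng):
        n = 120
        eta = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.08 * np.exp(0.8 * eta)))
        surv = _surv(t, np.ones(n, int))
        scores = pd.Series(eta, index=surv.sample_ids)
        horizon = float(np.quantile(t, 0.5))
        cal, nb = clinical_utility(scores, surv, horizon)
        assert (nb["treat_none"] == 0).all()
        prevalence = (t <= horizon).mean()
        assert nb.loc[nb["threshold"] == 0.0, "treat_all"].iloc[0] == pytest.approx(
            prevalence, abs=0.05)
        assert len(cal) == 3 and cal["n"].sum() == n

    def test_calibrated_model_tracks_km(self, rng):
        n = 400
        eta = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.08 * np.exp(0.8 * eta)))
        surv = _surv(t, np.ones(n, int))
        scores = pd.Series(eta, index=surv.sample_ids)
        cal, _ = clinical_utility(scores, surv, float(np.quantile(t, 0.4)))
        assert (cal["mean_predicted"] - cal["km_observed"]).abs().max() < 0.12


class TestMarkers:
    def test_affine_marker_is_perfectly_correlated(self, rng):
        s = pd.Series(rng.normal(size=30), index=[f"p{i}" for i in range(30)])
        r, p = correlate_markers(s, 3.0 * s - 2.0)
        assert r == pytest.approx(1.0)
        r, _ = correlate_markers(s, -0.5 * s + 1.0)
        assert r == pytest.approx(-1.0)

    def test_affine_invariance(self, rng):
        s = pd.Series(rng.normal(size=40), index=[f"p{i}" for i in range(40)])
        g = pd.Series(rng.normal(size=40), index=s.index)
        r1, p1 = correlate_markers(s, g)
        r2, p2 = correlate_markers(2.0 * s + 1.0, 0.1 * g - 7.0)
        assert r1 == pytest.approx(r2) and p1 == pytest.approx(p2)

    def test_zero_variance_rejected(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        with pytest.raises(ValueError, match="zero variance"):
            correlate_markers(s, pd.Series(1.0, index=list("abcd")))


class TestStratifyTwoMarkers:
    def test_partition_and_planted_hazard(self, rng):
        n = 200
        ids = [f"p{i}" for i in range(n)]
        risk_high = rng.random(n) < 0.5
        marker = pd.Series(rng.normal(size=n), index=ids)
        mhigh = marker > 0
        hazard = 0.05 * np.exp(1.2 * risk_high + 1.2 * mhigh.to_numpy())
        surv = _surv(rng.exponential(1 / hazard), np.ones(n, int), ids)
        scores = pd.Series(risk_high.astype(float), index=ids)
        res = stratify_two_markers(assign_groups(scores, 0.5), marker, 0.0, surv)
        assert res.groups.value_counts().sum() == n
        assert res.omnibus_p < 0.05
        horizon = float(np.quantile(surv.time, 0.4))
        km_at = {g: float(curve.iloc[:, 0][curve.index <= horizon].iloc[-1])
                 for g, curve in res.km_curves.items()}
        assert min(km_at, key=km_at.get) == "high/high"
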