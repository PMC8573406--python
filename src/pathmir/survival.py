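"""Prognostic miRNA signature construction and survival evaluation.

Pipeline: cross-cohort univariate Cox screening of candidate miRNAs
(unadjusted p < 0.1 with concordant hazard-ratio direction), an L1-penalized
Cox model with the penalty chosen by leave-one-out cross-validated partial
likelihood deviance (Verweij & van Houwelingen), a linear risk score
(sum of expression x coefficient), a maximally selected log-rank cutoff,
and the evaluation suite: Kaplan-Meier / log-rank, covariate-adjusted Cox,
time-dependent AUC with IPCW, Harrell's C, calibration and decision curves.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import concordance_index_censored, cumulative_dynamic_auc
from sksurv.util import Surv

from .iokit import ExpressionMatrix, SurvivalTable


@dataclass
class TermFit:
    coefficient: float
    hr: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class CoxFit:
    terms: dict[str, TermFit]
    converged: bool
    n: int
    n_events: int

    def __getitem__(self, term: str) -> TermFit:
        return self.terms[term]


@dataclass
class SignatureModel:
    """Sparse linear risk model: selected miRNAs, L1-Cox coefficients,
    penalty, risk cutoff."""

    mirna_ids: list[str]
    coefficients: list[float]
    lambda_: float
    cutoff: float | None = None
    training_cohort: str = ""

    def __post_init__(self) -> None:
        if len(self.mirna_ids) < 1:
            raise ValueError("signature must keep at least one miRNA")
        if any(c == 0 for c in self.coefficients):
            raise ValueError("signature coefficients must be nonzero")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "mirna_ids": self.mirna_ids,
                    "coefficients": list(map(float, self.coefficients)),
                    "lambda": self.lambda_,
                    "cutoff": self.cutoff,
                    "training_cohort": self.training_cohort,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["mirna_ids"], d["coefficients"], d["lambda"], d.get("cutoff"),
                   d.get("training_cohort", ""))


@dataclass
class RiskAssignment:
    """Per-sample risk score and high/low group (high iff score > cutoff)."""

    table: pd.DataFrame  # index sample_id; columns: score, group
    cutoff: float

    @property
    def scores(self) -> pd.Series:
        return self.table["score"]

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]


def assign_groups(scores: pd.Series, cutoff: float) -> RiskAssignment:
    group = np.where(scores.to_numpy() > cutoff, "high", "low")
    return RiskAssignment(pd.DataFrame({"score": scores, "group": group}), float(cutoff))


# ---------------------------------------------------------------------------
# Cox fits (lifelines; Efron ties)


def _cox_from_lifelines(cph: CoxPHFitter, n: int, n_events: int, converged: bool = True) -> CoxFit:
    terms = {}
    ci = cph.confidence_intervals_
    with np.errstate(over="ignore"):  # diverged fits can have huge CI bounds
        for term in cph.params_.index:
            coef = float(cph.params_[term])
            terms[term] = TermFit(
                coefficient=coef,
                hr=float(np.exp(coef)),
                ci_low=float(np.exp(ci.loc[term].iloc[0])),
                ci_high=float(np.exp(ci.loc[term].iloc[1])),
                p=float(cph.summary.loc[term, "p"]),
            )
    return CoxFit(terms=terms, converged=converged, n=n, n_events=n_events)


def _failed_fit(term_names, n, n_events) -> CoxFit:
    nan = float("nan")
    return CoxFit(
        {t: TermFit(nan, nan, nan, nan, nan) for t in term_names},
        converged=False, n=n, n_events=n_events,
    )


def _fit_cox(df: pd.DataFrame, term_names, n_events: int) -> CoxFit:
    """Fit a Cox model, downgrading monotone-likelihood / separation to a
    non-converged record instead of silently divergent coefficients."""
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cph.fit(df, duration_col="time", event_col="event")
    except Exception:
        return _failed_fit(term_names, len(df), n_events)
    diverged = any(
        "norm(delta) is still high" in str(w.message) for w in caught
    )
    fit = _cox_from_lifelines(cph, len(df), n_events, converged=not diverged)
    if any(np.isnan(t.p) or not np.isfinite(t.coefficient) for t in fit.terms.values()):
        fit.converged = False
    return fit


def univariate_cox(feature: pd.Series, surv: SurvivalTable, name: str = "feature") -> CoxFit:
    """Single-term Cox partial-likelihood fit; Wald p and 95% CI."""
    ids = surv.sample_ids
    df = pd.DataFrame(
        {name: feature.loc[ids].to_numpy(dtype=float), "time": surv.time, "event": surv.event},
        index=ids,
    )
    if surv.n_events < 2:
        raise ValueError("need >= 2 events")
    return _fit_cox(df, [name], surv.n_events)


def select_candidates(
    fits_by_cohort: dict[str, dict[str, CoxFit]],
    p_threshold: float = 0.1,
    mode: str = "all",
) -> list[str]:
    """Cross-cohort screen: keep miRNAs with concordant HR direction and
    unadjusted p below threshold in every cohort (``mode="all"``, default)
    or in at least one (``mode="any"``)."""
    if mode not in ("all", "any"):
        raise ValueError("mode must be 'all' or 'any'")
    cohorts = list(fits_by_cohort)
    universe = set(fits_by_cohort[cohorts[0]])
    for c in cohorts[1:]:
        if set(fits_by_cohort[c]) != universe:
            raise ValueError("cohorts must share the same miRNA universe")
    kept = []
    for mid in sorted(universe):
        fits = [fits_by_cohort[c][mid] for c in cohorts]
        if not all(f.converged for f in fits):
            continue
        coefs = [next(iter(f.terms.values())).coefficient for f in fits]
        ps = [next(iter(f.terms.values())).p for f in fits]
        if any(np.isnan(coefs)) or any(np.isnan(ps)):
            continue
        signs = {np.sign(c) for c in coefs}
        if len(signs) != 1 or signs == {0.0}:
            continue
        hit = [p < p_threshold for p in ps]
        if (mode == "all" and all(hit)) or (mode == "any" and any(hit)):
            kept.append(mid)
    return kept


# ---------------------------------------------------------------------------
# L1-penalized Cox with LOOCV deviance (Verweij & van Houwelingen)


def _cox_log_partial_likelihood(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                                beta: np.ndarray) -> float:
    """Breslow log partial likelihood at fixed coefficients."""
    eta = X @ beta
    order = np.argsort(-time, kind="stable")  # descending: prefix sum = risk set
    eta_o = eta[order]
    shift = eta_o.max()
    log_risk = np.log(np.cumsum(np.exp(eta_o - shift))) + shift
    # the risk set of an event at t_i spans the descending-order prefix up to
    # the last index sharing t_i (ties stay in the risk set)
    t_o = time[order]
    last_idx = np.searchsorted(-t_o, -t_o, side="right") - 1
    ev_o = event[order]
    idx = np.flatnonzero(ev_o == 1)
    return float(np.sum(eta_o[idx] - log_risk[last_idx[idx]]))


def _null_score_vector(X: np.ndarray, time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Gradient of the Breslow log partial likelihood at beta = 0."""
    n, p = X.shape
    order = np.argsort(-time, kind="stable")
    X_o = X[order]
    t_o = time[order]
    ev_o = event[order]
    csum = np.cumsum(X_o, axis=0)
    counts = np.arange(1, n + 1)
    last_idx = np.searchsorted(-t_o, -t_o, side="right") - 1
    g = np.zeros(p)
    for k in np.flatnonzero(ev_o == 1):
        j = last_idx[k]
        g += X_o[k] - csum[j] / counts[j]
    return g


def lambda_max(X: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Smallest penalty that zeroes every coefficient (glmnet scaling:
    objective = -logPL/n + lambda * ||beta||_1)."""
    g = _null_score_vector(X, time, event)
    return float(np.max(np.abs(g)) / len(time))


def default_lambda_grid(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                        n_lambda: int = 50, min_ratio: float = 0.01) -> np.ndarray:
    lmax = lambda_max(X, time, event)
    return np.geomspace(lmax * 1.001, lmax * min_ratio, n_lambda)


def _coxnet_path(X, y, alphas):
    """L1-Cox coefficients at every requested penalty.

    The glmnet-style solver stops its path early once the fit saturates, so
    refit on the uncovered tail until every requested alpha is solved."""
    alphas = np.asarray(alphas, dtype=float)
    coefs = np.full((X.shape[1], len(alphas)), np.nan)
    todo = np.argsort(-alphas)  # descending positions still lacking a solution
    while todo.size:
        grid = alphas[todo]
        model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=grid,
                                       fit_baseline_model=False,
                                       tol=1e-7, max_iter=100_000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, y)
        fitted = np.asarray(model.alphas_)
        done = []
        for pos_idx, j in enumerate(todo):
            k = np.flatnonzero(np.isclose(fitted, alphas[j], rtol=1e-8))
            if k.size:
                coefs[:, j] = model.coef_[:, k[0]]
                done.append(pos_idx)
        if not done:  # solver refused the whole grid; stop rather than loop
            raise RuntimeError("penalized Cox path failed to fit requested penalties")
        todo = np.delete(todo, done)
    return coefs


def lasso_cox_loocv(
    x: ExpressionMatrix,
    surv: SurvivalTable,
    lambda_grid=None,
    seed: int | None = None,
    training_cohort: str = "",
) -> tuple[SignatureModel, pd.DataFrame]:
    """L1-Cox path with the penalty chosen by leave-one-out cross-validated
    partial likelihood deviance.

    The held-out deviance contribution of subject i at penalty l is
    -2 * [logPL_full(beta_train) - logPL_train(beta_train)] (Verweij & van
    Houwelingen); lambda* minimizes the mean.  Returns the sparse model at
    lambda* (nonzero terms with their penalized coefficients) and the
    per-lambda deviance table.
    """
    if x.n_features < 2:
        raise ValueError("need >= 2 candidate features")
    ids = surv.sample_ids
    X = x.subset_samples(ids).values.T  # samples x features
    time, event = surv.time, surv.event
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(X, time, event)
    lambda_grid = np.asarray(sorted(lambda_grid, reverse=True), dtype=float)

    n = len(time)
    dev = np.zeros((n, len(lambda_grid)))
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        Xt, tt, et = X[keep], time[keep], event[keep]
        yt = Surv.from_arrays(event=et.astype(bool), time=tt)
        try:
            coefs = _coxnet_path(Xt, yt, lambda_grid)
        except Exception:
            dev[i, :] = np.nan
            continue
        for j in range(len(lambda_grid)):
            b = coefs[:, j]
            l_full = _cox_log_partial_likelihood(X, time, event, b)
            l_train = _cox_log_partial_likelihood(Xt, tt, et, b)
            dev[i, j] = -2.0 * (l_full - l_train)
    mean_dev = np.nanmean(dev, axis=0)
    j_star = int(np.nanargmin(mean_dev))
    lam = float(lambda_grid[j_star])

    full_coefs = _coxnet_path(X, y, lambda_grid)[:, j_star]
    nz = np.flatnonzero(full_coefs != 0)
    if nz.size == 0:
        raise ValueError("signature empty; relax grid")
    model = SignatureModel(
        mirna_ids=[x.feature_ids[k] for k in nz],
        coefficients=[float(full_coefs[k]) for k in nz],
        lambda_=lam,
        training_cohort=training_cohort,
    )
    table = pd.DataFrame({"lambda": lambda_grid, "mean_deviance": mean_dev})
    return model, table


def signature_score(m: ExpressionMatrix, model: SignatureModel) -> pd.Series:
    """Per-sample linear risk score: sum_i expression_i x coefficient_i."""
    missing = [g for g in model.mirna_ids if g not in m.data.index]
    if missing:
        raise KeyError(f"model miRNA(s) absent from matrix: {missing}")
    sub = m.data.loc[model.mirna_ids].to_numpy(dtype=float)
    scores = np.asarray(model.coefficients) @ sub
    return pd.Series(scores, index=m.sample_ids, name="score")


# ---------------------------------------------------------------------------
# cutoff search and group comparisons


def _logrank_statistic(high: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    res = logrank_test(time[high], time[~high], event[high], event[~high])
    return float(res.test_statistic)


def optimal_cutoff(scores: pd.Series, surv: SurvivalTable, min_prop: float = 0.1) -> float:
    """Maximally selected log-rank cutoff.

    Candidates are observed score values whose induced high (> cutoff) and
    low groups each hold at least ``min_prop`` of the cohort; the candidate
    with the largest log-rank statistic wins, ties going to the lower value.
    Note the subsequent log-rank p on the same data is optimistic; it is
    reported but not corrected.
    """
    ids = surv.sample_ids
    s = scores.loc[ids].to_numpy(dtype=float)
    if len(np.unique(s)) < 2:
        raise ValueError("need >= 2 distinct scores")
    time, event = surv.time, surv.event
    n = len(s)
    best_stat, best_cut = -np.inf, None
    for c in np.unique(s):  # ascending: first (lowest) cutoff wins ties
        high = s > c
        n_high = int(high.sum())
        if n_high < min_prop * n or (n - n_high) < min_prop * n:
            continue
        stat = _logrank_statistic(high, time, event)
        if stat > best_stat:
            best_stat, best_cut = stat, float(c)
    if best_cut is None:
        raise ValueError("no cutoff satisfies the minimum group proportion")
    return best_cut


@dataclass
class GroupComparison:
    hr: float
    hr_ci: tuple[float, float]
    logrank_p: float
    km_curves: dict[str, pd.DataFrame]
    cox: CoxFit


def km_logrank(assign: RiskAssignment, surv: SurvivalTable) -> GroupComparison:
    """Kaplan-Meier curves per risk group, two-group log-rank test, and the
    high-vs-low hazard ratio from a one-term Cox fit on the group indicator."""
    ids = surv.sample_ids
    groups = assign.groups.loc[ids]
    if groups.nunique() < 2:
        raise ValueError("both risk groups must be non-empty")
    time, event = surv.time, surv.event
    high = (groups == "high").to_numpy()

    curves = {}
    for label, mask in (("high", high), ("low", ~high)):
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=label)
        curves[label] = kmf.survival_function_

    lr = logrank_test(time[high], time[~high], event[high], event[~high])
    ind = pd.Series(high.astype(float), index=ids, name="high_risk")
    cox = univariate_cox(ind, surv, name="high_risk")
    t = cox["high_risk"]
    nan = float("nan")
    # a diverged indicator fit (complete separation) has no finite HR
    hr, ci = (t.hr, (t.ci_low, t.ci_high)) if cox.converged else (nan, (nan, nan))
    return GroupComparison(hr=hr, hr_ci=ci,
                           logrank_p=float(lr.p_value), km_curves=curves, cox=cox)


def multivariable_cox(score: pd.Series, covariates: pd.DataFrame, surv: SurvivalTable) -> CoxFit:
    """Covariate-adjusted Cox fit of the risk score.

    Rejects perfectly collinear predictor pairs up front (|r| = 1)."""
    ids = surv.sample_ids
    df = pd.DataFrame({"score": score.loc[ids].to_numpy(dtype=float)}, index=ids)
    for col in covariates.columns:
        df[col] = pd.to_numeric(covariates.loc[ids, col], errors="raise").to_numpy()
    cols = list(df.columns)
    corr = np.corrcoef(df.to_numpy().T)
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            if abs(corr[a, b]) > 1 - 1e-10:
                raise ValueError(f"collinear predictors: {cols[a]!r} and {cols[b]!r}")
    df["time"], df["event"] = surv.time, surv.event
    return _fit_cox(df, cols, surv.n_events)


# ---------------------------------------------------------------------------
# discrimination, calibration, decision curves


@dataclass
class PerformanceMetrics:
    auc_at_times: dict[float, float]
    mean_auc: float
    c_index: float
    c_index_ci: tuple[float, float]
    n_concordant_pairs: int


def performance_metrics(scores: pd.Series, surv: SurvivalTable, times) -> PerformanceMetrics:
    """Time-dependent cumulative/dynamic AUC with IPCW (Kaplan-Meier
    censoring weights) and Harrell's C with a normal-approximation 95% CI."""
    ids = surv.sample_ids
    s = scores.loc[ids].to_numpy(dtype=float)
    time, event = surv.time, surv.event
    times = np.asarray(list(times), dtype=float)
    if (times >= time.max()).any():
        raise ValueError("each requested time must be below the maximum follow-up")
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    auc, mean_auc = cumulative_dynamic_auc(y, y, s, times)
    c, conc, disc, tied_risk, _ = concordance_index_censored(event.astype(bool), time, s)
    pairs = conc + disc + tied_risk
    if pairs == 0:
        raise ValueError("no usable (comparable) pairs for concordance")
    se = np.sqrt(c * (1 - c) / pairs)
    ci = (max(0.0, c - 1.96 * se), min(1.0, c + 1.96 * se))
    return PerformanceMetrics(
        auc_at_times={float(t): float(a) for t, a in zip(times, auc)},
        mean_auc=float(mean_auc),
        c_index=float(c),
        c_index_ci=ci,
        n_concordant_pairs=int(pairs),
    )


def _km_survival_at(time: np.ndarray, event: np.ndarray, horizon: float) -> float:
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    return float(kmf.predict(horizon))


def clinical_utility(
    scores: pd.Series,
    surv: SurvivalTable,
    time_horizon: float,
    threshold_grid=None,
    n_bins: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Calibration table and decision-curve net benefit at one horizon.

    A Cox fit on the score (Breslow baseline) converts scores to event
    probabilities at the horizon.  Calibration bins samples into score
    tertiles and compares mean predicted probability with the KM-observed
    event fraction.  Net benefit NB(pt) = TP/n - FP/n * pt/(1-pt), with TP/FP
    fractions estimated KM-style inside the treated group; treat-all and
    treat-none references included.
    """
    ids = surv.sample_ids
    s = scores.loc[ids].to_numpy(dtype=float)
    time, event = surv.time, surv.event
    if time_horizon >= time.max():
        raise ValueError("time horizon beyond follow-up")
    df = pd.DataFrame({"score": s, "time": time, "event": event}, index=ids)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    surv_prob = cph.predict_survival_function(df[["score"]], times=[time_horizon])
    p_event = 1.0 - surv_prob.iloc[0].to_numpy(dtype=float)

    # calibration by score tertile
    qs = pd.qcut(pd.Series(s, index=ids), q=n_bins, labels=False, duplicates="drop")
    rows = []
    for b in sorted(qs.dropna().unique()):
        mask = (qs == b).to_numpy()
        observed = 1.0 - _km_survival_at(time[mask], event[mask], time_horizon)
        rows.append({"bin": int(b), "n": int(mask.sum()),
                     "mean_predicted": float(p_event[mask].mean()),
                     "km_observed": float(observed)})
    calibration = pd.DataFrame(rows)

    if threshold_grid is None:
        threshold_grid = np.arange(0.0, 1.0, 0.05)
    n = len(s)
    prevalence = 1.0 - _km_survival_at(time, event, time_horizon)
    nb_rows = []
    for pt in threshold_grid:
        odds = pt / (1.0 - pt) if pt < 1 else np.inf
        treated = p_event >= pt
        if treated.sum() == 0:
            nb_model = 0.0
        else:
            risk_treated = 1.0 - _km_survival_at(time[treated], event[treated], time_horizon)
            frac = treated.sum() / n
            nb_model = frac * risk_treated - frac * (1.0 - risk_treated) * odds
        nb_all = prevalence - (1.0 - prevalence) * odds
        nb_rows.append({"threshold": float(pt), "model": float(nb_model),
                        "treat_all": float(nb_all), "treat_none": 0.0})
    return calibration, pd.DataFrame(nb_rows)


def correlate_markers(scores: pd.Series, expr_of_gene: pd.Series) -> tuple[float, float]:
    """Pearson correlation (and two-sided p) of the risk score with one
    gene's expression."""
    common = scores.index.intersection(expr_of_gene.index)
    if len(common) < 4:
        raise ValueError("need n >= 4 shared samples")
    a = scores.loc[common].to_numpy(dtype=float)
    b = expr_of_gene.loc[common].to_numpy(dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


@dataclass
class StratificationResult:
    groups: pd.Series
    omnibus_p: float
    pairwise_p: dict[tuple[str, str], float]
    km_curves: dict[str, pd.DataFrame]
    collapsed: bool


def stratify_two_markers(
    assign: RiskAssignment,
    marker: pd.Series,
    marker_cutoff: float,
    surv: SurvivalTable,
) -> StratificationResult:
    """Four-group survival stratification: {risk high/low} x {marker high/low}.

    Omnibus log-rank across the non-empty groups (a warning is issued and the
    empty groups dropped if fewer than four are populated), plus pairwise
    two-group log-rank p-values and per-group KM curves."""
    ids = surv.sample_ids
    risk = assign.groups.loc[ids]
    mhigh = marker.loc[ids].to_numpy(dtype=float) > marker_cutoff
    labels = pd.Series(
        [f"{r}/{'high' if m else 'low'}" for r, m in zip(risk, mhigh)], index=ids
    )
    counts = labels.value_counts()
    collapsed = len(counts) < 4
    if collapsed:
        warnings.warn("fewer than four populated groups; omnibus over populated ones")
    if len(counts) < 2:
        raise ValueError("need >= 2 populated groups")
    time, event = surv.time, surv.event
    res = multivariate_logrank_test(time, labels.to_numpy(), event)
    curves = {}
    pairwise = {}
    names = sorted(counts.index)
    for g in names:
        mask = (labels == g).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=g)
        curves[g] = kmf.survival_function_
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            ma = (labels == names[a]).to_numpy()
            mb = (labels == names[b]).to_numpy()
            lr = logrank_test(time[ma], time[mb], event[ma], event[mb])
            pairwise[(names[a], names[b])] = float(lr.p_value)
    return StratificationResult(labels, float(res.p_value), pairwise, curves, collapsed)
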