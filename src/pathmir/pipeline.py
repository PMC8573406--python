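"""End-to-end orchestration: modulator discovery across cohorts and
signature construction with cross-cohort validation.

Both drivers operate on in-memory cohort objects and return plain result
tables plus a run manifest (config snapshot, per-stage feature counts,
wall-clock).  The CLI wraps these with file I/O.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel

from . import __version__
from .iokit import (
    ExpressionMatrix,
    GeneSetCollection,
    PurityVector,
    SurvivalTable,
    filter_low_expression,
    harmonize_cohorts,
    zscore_by_feature,
)
from .modulators import ModulatorRecord, modulator_scan
from .survival import (
    SignatureModel,
    assign_groups,
    km_logrank,
    lasso_cox_loocv,
    multivariable_cox,
    optimal_cutoff,
    performance_metrics,
    select_candidates,
    signature_score,
    univariate_cox,
)


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, with the published defaults."""

    max_zero_fraction: float = 0.5
    tes_threshold: float = 0.995
    fdr_threshold: float = 0.05
    p_screen: float = 0.1
    screen_mode: str = "all"
    min_prop: float = 0.1
    differential_fdr: float = 0.05
    differential_difference: float = 0.5
    pathway_cox_p: float = 0.05
    n_perm: int = 10_000
    gsea_weight: float = 1.0
    min_set_size: int = 5
    seed: int = 1
    eval_times: list[float] | None = None

    def __post_init__(self) -> None:
        for name in ("max_zero_fraction", "tes_threshold", "fdr_threshold",
                     "p_screen", "min_prop", "differential_fdr", "pathway_cox_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass
class DiscoveryCohort:
    name: str
    mirna: ExpressionMatrix
    mrna: ExpressionMatrix
    purity: PurityVector


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, count: int, seconds: float) -> None:
        self.stages.append({"stage": stage, "count": int(count), "seconds": round(seconds, 3)})

    def to_dict(self) -> dict:
        return {"config": self.config, "version": self.version, "stages": self.stages}


def records_to_frame(records: list[ModulatorRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna_id": [r.mirna_id for r in records],
            "es": [r.result.es for r in records],
            "p_perm": [r.result.p_raw for r in records],
            "fdr": [r.result.fdr for r in records],
            "tes": [r.tes for r in records],
            "is_modulator": [r.is_modulator for r in records],
        }
    ).set_index("mirna_id")


def run_discovery(
    cohorts: list[DiscoveryCohort],
    gene_set,
    config: RunConfig,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], RunManifest]:
    """Filter, harmonize, scan each cohort, intersect the flagged miRNAs.

    Returns (intersection table, per-cohort tables, manifest).
    """
    manifest = RunManifest(config=vars(config).copy(), version=__version__)
    t0 = _time.perf_counter()
    filtered = [
        DiscoveryCohort(
            c.name,
            filter_low_expression(c.mirna, config.max_zero_fraction),
            c.mrna,
            c.purity,
        )
        for c in cohorts
    ]
    manifest.record("filter_low_expression", sum(c.mirna.n_features for c in filtered),
                    _time.perf_counter() - t0)

    t0 = _time.perf_counter()
    if len(filtered) > 1:
        harmonized = harmonize_cohorts([c.mirna for c in filtered])
        filtered = [DiscoveryCohort(c.name, h, c.mrna, c.purity)
                    for c, h in zip(filtered, harmonized)]
    manifest.record("harmonize_cohorts", filtered[0].mirna.n_features,
                    _time.perf_counter() - t0)

    per_cohort: dict[str, pd.DataFrame] = {}
    flagged_sets = []
    for k, c in enumerate(filtered):
        t0 = _time.perf_counter()
        records, skipped = modulator_scan(
            c.mirna, c.mrna, c.purity, gene_set,
            n_perm=config.n_perm, weight=config.gsea_weight,
            seed=config.seed + k, tes_threshold=config.tes_threshold,
            fdr_threshold=config.fdr_threshold, min_set_size=config.min_set_size,
        )
        frame = records_to_frame(records)
        per_cohort[c.name] = frame
        flagged_sets.append(set(frame.index[frame["is_modulator"]]))
        manifest.record(f"modulator_scan[{c.name}]", len(records),
                        _time.perf_counter() - t0)

    shared = sorted(set.intersection(*flagged_sets)) if flagged_sets else []
    rows = []
    for mid in shared:
        rows.append({"mirna_id": mid,
                     **{f"tes_{name}": per_cohort[name].loc[mid, "tes"] for name in per_cohort}})
    result = pd.DataFrame(rows).set_index("mirna_id") if rows else pd.DataFrame(
        index=pd.Index([], name="mirna_id"))
    manifest.record("intersection", len(shared), 0.0)
    return result, per_cohort, manifest


# ---------------------------------------------------------------------------
# signature pipeline


def _finite_or_none(x) -> float | None:
    return float(x) if x is not None and np.isfinite(x) else None


class CohortEvaluation(BaseModel):
    n: int
    n_events: int
    cutoff: float
    hr_high_vs_low: float | None  # None when the indicator fit separates
    hr_ci: tuple[float | None, float | None]
    logrank_p: float
    c_index: float
    c_index_ci: tuple[float, float]
    auc_at_times: dict[str, float]
    adjusted_score_hr: float | None = None
    adjusted_score_p: float | None = None


class SignatureReport(BaseModel):
    """Packaged schema of the signature-evaluation report."""

    model_mirnas: list[str]
    coefficients: list[float]
    lambda_: float
    training_cohort: str
    candidates: list[str]
    seed: int
    cohorts: dict[str, CohortEvaluation]


def run_signature(
    discovery: tuple[str, ExpressionMatrix, SurvivalTable],
    validation: tuple[str, ExpressionMatrix, SurvivalTable],
    modulators: list[str],
    config: RunConfig,
    covariates: dict[str, pd.DataFrame] | None = None,
) -> tuple[SignatureModel, SignatureReport, RunManifest]:
    """Two-cohort screen -> L1-Cox (LOOCV penalty) on discovery -> score,
    cutoff, and survival evaluation on both cohorts.

    Coefficients are frozen from the discovery cohort; z-scoring is done per
    application cohort.
    """
    if not modulators:
        raise ValueError("modulator list is empty")
    manifest = RunManifest(config=vars(config).copy(), version=__version__)
    named = {discovery[0]: discovery, validation[0]: validation}

    t0 = _time.perf_counter()
    zscored: dict[str, ExpressionMatrix] = {}
    fits_by_cohort: dict[str, dict] = {}
    for name, (label, expr, surv) in named.items():
        present = [m for m in modulators if m in expr.data.index]
        if len(present) < len(modulators):
            missing = sorted(set(modulators) - set(present))
            raise KeyError(f"cohort {name!r} lacks modulator miRNA(s): {missing}")
        z = zscore_by_feature(expr.subset_features(modulators).subset_samples(surv.sample_ids))
        zscored[name] = z
        fits_by_cohort[name] = {
            mid: univariate_cox(z.data.loc[mid], surv, name=mid) for mid in modulators
        }
    manifest.record("univariate_screen", len(modulators), _time.perf_counter() - t0)

    candidates = select_candidates(fits_by_cohort, config.p_screen, config.screen_mode)
    manifest.record("select_candidates", len(candidates), 0.0)
    if not candidates:
        table = {
            c: {m: next(iter(f.terms.values())).p for m, f in fits.items()}
            for c, fits in fits_by_cohort.items()
        }
        raise ValueError(f"no candidates pass the screen; per-miRNA p-values: {table}")

    disc_name, _, disc_surv = discovery
    t0 = _time.perf_counter()
    model, dev_table = lasso_cox_loocv(
        zscored[disc_name].subset_features(candidates), disc_surv,
        seed=config.seed, training_cohort=disc_name,
    )
    manifest.record("lasso_cox_loocv", len(model.mirna_ids), _time.perf_counter() - t0)

    disc_scores = signature_score(zscored[disc_name], model)
    cutoff = optimal_cutoff(disc_scores, disc_surv, config.min_prop)
    model.cutoff = cutoff

    evaluations: dict[str, CohortEvaluation] = {}
    for name, (label, expr, surv) in named.items():
        t0 = _time.perf_counter()
        scores = signature_score(zscored[name], model)
        cut = optimal_cutoff(scores, surv, config.min_prop) if name != disc_name else cutoff
        assign = assign_groups(scores, cut)
        comp = km_logrank(assign, surv)
        times = config.eval_times or list(
            np.quantile(surv.time[surv.event == 1], [0.25, 0.5, 0.75])
        )
        times = [t for t in times if t < surv.time.max()]
        perf = performance_metrics(scores, surv, times)
        adj_hr = adj_p = None
        if covariates and name in covariates:
            fit = multivariable_cox(scores, covariates[name], surv)
            if fit.converged:
                adj_hr, adj_p = fit["score"].hr, fit["score"].p
        evaluations[name] = CohortEvaluation(
            n=len(surv.sample_ids),
            n_events=surv.n_events,
            cutoff=float(cut),
            hr_high_vs_low=_finite_or_none(comp.hr),
            hr_ci=(_finite_or_none(comp.hr_ci[0]), _finite_or_none(comp.hr_ci[1])),
            logrank_p=comp.logrank_p,
            c_index=perf.c_index,
            c_index_ci=perf.c_index_ci,
            auc_at_times={f"{t:g}": a for t, a in perf.auc_at_times.items()},
            adjusted_score_hr=adj_hr,
            adjusted_score_p=adj_p,
        )
        manifest.record(f"evaluate[{name}]", len(surv.sample_ids), _time.perf_counter() - t0)

    report = SignatureReport(
        model_mirnas=model.mirna_ids,
        coefficients=model.coefficients,
        lambda_=model.lambda_,
        training_cohort=model.training_cohort,
        candidates=candidates,
        seed=config.seed,
        cohorts=evaluations,
    )
    return model, report, manifest
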