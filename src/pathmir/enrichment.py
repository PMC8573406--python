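"""Sample-level pathway activity (ssGSEA) and the pathway screen.

Activity is scored per sample with the single-sample GSEA statistic: genes
are ranked within the sample, and the score is the summed gap between the
weighted in-set ECDF and the out-of-set ECDF along the ranking.  The screen
combines differential activity between tumor and normal samples (Welch test,
BH-FDR, |difference| threshold) with a per-pathway univariate Cox filter on
overall survival.  Also provides the 18-gene T-cell-inflamed signature (TIS)
score used to anticipate checkpoint-blockade response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .iokit import ExpressionMatrix, GeneSetCollection, SurvivalTable
from .survival import CoxFit, univariate_cox


@dataclass
class ActivityMatrix:
    """Gene-set x sample activity scores."""

    data: pd.DataFrame  # index = set names, columns = sample ids
    alpha: float
    normalized: bool

    @property
    def set_names(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class PathwayScreenResult:
    set_name: str
    activity_difference: float
    fdr: float
    cox_hr: float
    cox_p: float
    passes_differential: bool
    passes_cox: bool
    cox_converged: bool = True


def _ssgsea_one_sample(expr: np.ndarray, gene_ids: np.ndarray, hit_masks: dict,
                       alpha: float) -> dict[str, float]:
    n = len(expr)
    ranks = stats.rankdata(expr, method="average")  # 1 = lowest
    # descending expression; ties broken lexicographically by gene id
    order = np.lexsort((gene_ids, -expr))
    r_sorted = ranks[order] ** alpha
    out = {}
    for name, mask in hit_masks.items():
        hits = mask[order]
        n_hit = int(hits.sum())
        hit_w = np.where(hits, r_sorted, 0.0)
        p_in = np.cumsum(hit_w) / hit_w.sum()
        p_out = np.cumsum(~hits) / (n - n_hit)
        out[name] = float(np.sum(p_in - p_out))
    return out


def ssgsea_scores(
    m: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
    min_set_size: int = 2,
) -> ActivityMatrix:
    """Single-sample enrichment score of every gene set in every sample.

    Rank-based, hence invariant to monotone within-sample transforms.  With
    ``normalize`` the whole matrix is divided by its (max - min) range, the
    usual presentation for cross-set comparison.
    """
    if m.n_samples < 2:
        raise ValueError("need >= 2 samples")
    gene_ids = np.array(m.feature_ids)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    hit_masks = {}
    for name in sets.names():
        mask = np.zeros(len(gene_ids), dtype=bool)
        mapped = [gene_pos[g] for g in sets[name] if g in gene_pos]
        if len(mapped) < min_set_size:
            warnings.warn(f"gene set {name!r}: only {len(mapped)} mapped genes; skipped")
            continue
        if len(mapped) == len(gene_ids):
            warnings.warn(f"gene set {name!r} covers every gene; skipped")
            continue
        mask[mapped] = True
        hit_masks[name] = mask
    if not hit_masks:
        raise ValueError("no scorable gene sets")

    values = m.values
    cols = {}
    for j, sid in enumerate(m.sample_ids):
        cols[sid] = _ssgsea_one_sample(values[:, j], gene_ids, hit_masks, alpha)
    df = pd.DataFrame(cols).loc[list(hit_masks)]
    if normalize:
        rng_span = df.to_numpy().max() - df.to_numpy().min()
        if rng_span > 0:
            df = df / rng_span
    return ActivityMatrix(df, alpha=alpha, normalized=normalize)


def differential_activity(a: ActivityMatrix, groups: pd.Series) -> pd.DataFrame:
    """Per-set Welch test of tumor vs normal activity with BH-FDR.

    ``groups`` maps sample id -> "tumor"/"normal".  Difference is
    mean(tumor) - mean(normal); a ratio is ill-defined for signed scores.
    """
    g = groups.loc[a.sample_ids]
    tumor = (g == "tumor").to_numpy()
    normal = (g == "normal").to_numpy()
    if tumor.sum() < 2 or normal.sum() < 2:
        raise ValueError("each group needs >= 2 samples")
    values = a.data.to_numpy()
    diffs, ps = [], []
    for row in values:
        t, n = row[tumor], row[normal]
        diffs.append(t.mean() - n.mean())
        if np.std(t) == 0 and np.std(n) == 0:
            ps.append(1.0 if t.mean() == n.mean() else 0.0)
        else:
            ps.append(float(stats.ttest_ind(t, n, equal_var=False).pvalue))
    fdr = multipletests(ps, method="fdr_bh")[1]
    return pd.DataFrame(
        {"difference": diffs, "p": ps, "fdr": fdr}, index=a.set_names
    )


def pathway_cox_screen(
    a: ActivityMatrix,
    surv: SurvivalTable,
    differential: pd.DataFrame | None = None,
    fdr_threshold: float = 0.05,
    difference_threshold: float = 0.5,
    cox_p_threshold: float = 0.05,
) -> list[PathwayScreenResult]:
    """Univariate Cox on each pathway's continuous activity score.

    When ``differential`` (from :func:`differential_activity`) is supplied
    the combined tumor-vs-normal flags are filled; otherwise the
    differential fields are NaN/False.  Non-converged fits are flagged, not
    dropped.
    """
    if surv.n_events < 10:
        warnings.warn("fewer than 10 events; pathway Cox screen is unstable")
    ids = surv.sample_ids
    out = []
    for name in a.set_names:
        score = a.data.loc[name, ids]
        if score.std() == 0:
            out.append(PathwayScreenResult(name, *_diff_fields(differential, name),
                                           float("nan"), float("nan"),
                                           passes_differential=False, passes_cox=False,
                                           cox_converged=False))
            continue
        fit = univariate_cox(score, surv, name="activity")
        term = fit["activity"]
        diff, fdr = _diff_fields(differential, name)
        passes_diff = bool(np.isfinite(fdr) and fdr < fdr_threshold
                           and abs(diff) > difference_threshold)
        passes_cox = bool(fit.converged and np.isfinite(term.p) and term.p < cox_p_threshold)
        out.append(PathwayScreenResult(
            name, diff, fdr, term.hr, term.p,
            passes_differential=passes_diff, passes_cox=passes_cox,
            cox_converged=fit.converged,
        ))
    return out


def _diff_fields(differential: pd.DataFrame | None, name: str) -> tuple[float, float]:
    if differential is None or name not in differential.index:
        return float("nan"), float("nan")
    row = differential.loc[name]
    return float(row["difference"]), float(row["fdr"])


# ---------------------------------------------------------------------------
# T-cell-inflamed signature


def load_tis_genes() -> list[str]:
    """The 18-gene T-cell-inflamed signature (Ayers et al., J Clin Invest
    2017); override by passing your own list to :func:`tis_score`."""
    text = resources.files("pathmir.data").joinpath("tis_genes.txt").read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def load_immune_cell_sets() -> GeneSetCollection:
    """Synthetic stand-in marker sets for 28 immune cell types (canonical
    cell-type names, small illustrative marker lists).  Real analyses should
    substitute a published signature GMT."""
    from .iokit import read_gmt

    path = resources.files("pathmir.data").joinpath("immune_cells_28.synthetic.gmt")
    with resources.as_file(path) as p:
        return read_gmt(p)


def tis_score(
    m: ExpressionMatrix,
    tis_genes: list[str] | None = None,
    log_transform: bool | None = None,
) -> pd.Series:
    """Mean per-gene z-score of log-scale expression over the TIS genes.

    ``log_transform=None`` applies log2(x+1) automatically for count/TPM/RPM
    matrices and leaves array-intensity/z-score values as-is.  Genes absent
    from the matrix or constant across samples are dropped with a warning.
    """
    genes = tis_genes if tis_genes is not None else load_tis_genes()
    present = [g for g in genes if g in m.data.index]
    if not present:
        raise ValueError("none of the signature genes are present")
    if len(present) < len(genes):
        warnings.warn(f"{len(genes) - len(present)} of {len(genes)} signature genes absent")
    values = m.data.loc[present].to_numpy(dtype=float)
    if log_transform is None:
        log_transform = m.unit_tag in ("count", "TPM", "RPM")
    if log_transform:
        values = np.log2(values + 1.0)
    sd = values.std(axis=1, ddof=1)
    usable = sd > 0
    if not usable.any():
        raise ValueError("all signature genes have zero variance")
    if not usable.all():
        dropped = [present[i] for i in np.flatnonzero(~usable)]
        warnings.warn(f"zero-variance signature gene(s) dropped: {dropped}")
    v = values[usable]
    z = (v - v.mean(axis=1, keepdims=True)) / v.std(axis=1, ddof=1, keepdims=True)
    return pd.Series(z.mean(axis=0), index=m.sample_ids, name="tis")
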