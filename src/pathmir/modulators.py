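"""Purity-adjusted miRNA -> pathway modulator discovery.

The three-step framework: (1) for one miRNA, rank every mRNA by a signed
-log p rank index derived from the first-order partial correlation between
miRNA and mRNA given tumor purity; (2) run a weighted Kolmogorov-Smirnov
(preranked GSEA) test of a pathway gene set against the ranked list, with a
gene-label permutation p-value; (3) collapse significance and direction into
a single enrichment score TES = (1 - 2p) * sign(ES) in [-1, 1] and flag
miRNAs with |TES| above threshold and FDR below threshold as pathway-derived
modulators.

Tumor purity confounds bulk miRNA-mRNA correlations (both track the
malignant-cell fraction); the first-order partial correlation removes its
linear effect before ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .iokit import ExpressionMatrix, PurityVector

P_FLOOR = 1e-300
PCC_CLAMP = 1.0 - 1e-12


class DegenerateConfounderError(ValueError):
    """Purity is perfectly collinear with an expression vector."""


@dataclass
class GeneAssociation:
    """One (miRNA, mRNA) pair: raw correlations, purity-adjusted PCC, p, rank index."""

    mirna_id: str
    mrna_id: str
    r_mim: float
    r_mip: float
    r_mp: float
    pcc: float
    p_value: float
    rank_index: float


@dataclass
class RankedList:
    """mRNAs ordered by descending rank index for one miRNA."""

    mirna_id: str
    gene_ids: list[str]
    rank_values: np.ndarray
    associations: list[GeneAssociation] | None = None

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class GseaResult:
    es: float
    p_perm: float
    fdr: float
    n_perm: int
    p_raw: float | None = None  # alias kept alongside BH-adjusted p_perm


@dataclass
class ModulatorRecord:
    mirna_id: str
    result: GseaResult
    tes: float
    is_modulator: bool


@dataclass
class SkippedRecord:
    mirna_id: str
    reason: str


def partial_correlation(x, y, z) -> float:
    """First-order partial Pearson correlation of x and y given z.

    (R_xy - R_xz * R_yz) / (sqrt(1 - R_xz^2) * sqrt(1 - R_yz^2)),
    clamped into [-1, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = len(x)
    if not (len(y) == n == len(z)) or n < 4:
        raise ValueError("x, y, z must have equal length n >= 4")
    for name, v in (("x", x), ("y", y), ("z", z)):
        if np.std(v) == 0:
            raise ValueError(f"{name} has zero variance")
    r_xy = _pearson(x, y)
    r_xz = _pearson(x, z)
    r_yz = _pearson(y, z)
    if abs(r_xz) >= 1.0 or abs(r_yz) >= 1.0:
        raise DegenerateConfounderError("confounder perfectly correlated with input")
    pcc = (r_xy - r_xz * r_yz) / (np.sqrt(1 - r_xz**2) * np.sqrt(1 - r_yz**2))
    return float(np.clip(pcc, -1.0, 1.0))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def correlation_pvalue(pcc: float, n: int, method: str = "ratio") -> float:
    """Two-sided normal p-value for a (partial) correlation coefficient.

    ``ratio`` (default): z = pcc * sqrt(n - 3) / sqrt(1 - pcc^2).
    ``fisher``: z = atanh(pcc) * sqrt(n - 3), for sensitivity analysis.
    Result floored at 1e-300.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if abs(pcc) >= 1.0:
        import warnings

        warnings.warn("|pcc| = 1; returning the p-value floor")
        return P_FLOOR
    if method == "ratio":
        z = pcc * np.sqrt(n - 3) / np.sqrt(1 - pcc**2)
    elif method == "fisher":
        z = np.arctanh(pcc) * np.sqrt(n - 3)
    else:
        raise ValueError(f"unknown method {method!r}")
    p = 2.0 * stats.norm.cdf(-abs(z))
    return float(max(p, P_FLOOR))


def rank_index(p: float, pcc: float) -> float:
    """Signed -log p statistic ordering mRNAs: -ln(p) * sign(pcc)."""
    if p <= 0:
        raise ValueError("p must be positive")
    if pcc == 0:
        return 0.0
    return float(-np.log(p) * np.sign(pcc))


def _association_table(
    mirna_values: np.ndarray,
    mrna_values: np.ndarray,
    purity: np.ndarray,
    p_method: str = "ratio",
):
    """Vectorized PCC / p / rank-index for all (miRNA, mRNA) pairs.

    Returns (r_mim, r_mip, r_mp, pcc, p, ri); r_mim/pcc/p/ri are
    (n_mirna, n_mrna) arrays.
    """
    n = mirna_values.shape[1]
    if n < 4:
        raise ValueError("need n >= 4 samples")

    def _std_rows(a):
        c = a - a.mean(axis=1, keepdims=True)
        norms = np.sqrt((c * c).sum(axis=1))
        if (norms == 0).any():
            raise ValueError("zero-variance feature encountered")
        return c / norms[:, None]

    mi_s = _std_rows(mirna_values)
    m_s = _std_rows(mrna_values)
    pz = purity - purity.mean()
    pn = np.sqrt(pz @ pz)
    r_mim = mi_s @ m_s.T
    if pn == 0:
        # constant purity: nothing to adjust for; PCC falls back to Pearson
        r_mip = np.zeros(mirna_values.shape[0])
        r_mp = np.zeros(mrna_values.shape[0])
    else:
        pz = pz / pn
        r_mip = mi_s @ pz
        r_mp = m_s @ pz
    r_mip = np.clip(r_mip, -PCC_CLAMP, PCC_CLAMP)
    r_mp = np.clip(r_mp, -PCC_CLAMP, PCC_CLAMP)

    denom = np.sqrt(1 - r_mip**2)[:, None] * np.sqrt(1 - r_mp**2)[None, :]
    pcc = (r_mim - np.outer(r_mip, r_mp)) / denom
    pcc = np.clip(pcc, -PCC_CLAMP, PCC_CLAMP)

    if p_method == "ratio":
        z = pcc * np.sqrt(n - 3) / np.sqrt(1 - pcc**2)
    elif p_method == "fisher":
        z = np.arctanh(pcc) * np.sqrt(n - 3)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    p = np.maximum(2.0 * stats.norm.cdf(-np.abs(z)), P_FLOOR)
    ri = -np.log(p) * np.sign(pcc)
    return r_mim, r_mip, r_mp, pcc, p, ri


def build_ranked_list(
    mirna_id: str,
    mi_row: np.ndarray,
    mrna: ExpressionMatrix,
    purity: PurityVector,
    p_method: str = "ratio",
    keep_associations: bool = True,
) -> RankedList:
    """Rank all mRNAs for one miRNA by descending rank index.

    Ties broken lexicographically by gene id for determinism.
    """
    mi_row = np.asarray(mi_row, dtype=float)
    pvec = purity.aligned_to(mrna.sample_ids)
    if len(mi_row) != mrna.n_samples:
        raise ValueError("miRNA vector and mRNA matrix sample counts differ")
    r_mim, r_mip, r_mp, pcc, p, ri = _association_table(
        mi_row[None, :], mrna.values, pvec, p_method
    )
    genes = np.array(mrna.feature_ids)
    ri = ri[0]
    order = np.lexsort((genes, -ri))
    assoc = None
    if keep_associations:
        assoc = [
            GeneAssociation(
                mirna_id, genes[j], float(r_mim[0, j]), float(r_mip[0]),
                float(r_mp[j]), float(pcc[0, j]), float(p[0, j]), float(ri[j]),
            )
            for j in order
        ]
    return RankedList(mirna_id, [str(g) for g in genes[order]], ri[order], assoc)


# ---------------------------------------------------------------------------
# weighted KS enrichment


def _walk_steps(rank_values: np.ndarray, hit_mask: np.ndarray, weight: float) -> np.ndarray:
    """Per-position increments of the weighted KS running sum."""
    n = len(rank_values)
    n_hit = int(hit_mask.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("gene set must hit a strict subset of the list")
    w = np.abs(rank_values) ** weight
    hit_w = np.where(hit_mask, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hits carry zero rank statistic; fall back to equal mass
        hit_w = hit_mask.astype(float)
        total = hit_w.sum()
    steps = hit_w / total
    steps[~hit_mask] = -1.0 / (n - n_hit)
    return steps


def enrichment_score(rank_values: np.ndarray, hit_mask: np.ndarray, weight: float = 1.0) -> float:
    """Signed maximal deviation of the running sum; the extremum of larger
    magnitude wins (positive taken on an exact tie)."""
    walk = np.cumsum(_walk_steps(rank_values, hit_mask, weight))
    hi = walk.max()
    lo = walk.min()
    return float(hi if abs(hi) >= abs(lo) else lo)


def _permutation_es(
    rank_values: np.ndarray, n_hit: int, weight: float, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """ES of ``n_perm`` size-matched random gene subsets, vectorized."""
    n = len(rank_values)
    w = np.abs(rank_values) ** weight
    # random size-n_hit subsets via partial argsort of uniform keys
    keys = rng.random((n_perm, n))
    hit_idx = np.argpartition(keys, n_hit - 1, axis=1)[:, :n_hit]
    rows = np.arange(n_perm)[:, None]
    hw = w[hit_idx]
    sums = hw.sum(axis=1)
    zero = sums == 0
    if zero.any():  # degenerate all-zero weights: equal mass per hit
        hw[zero] = 1.0
        sums[zero] = n_hit
    steps = np.full((n_perm, n), -1.0 / (n - n_hit))
    steps[rows, hit_idx] = hw / sums[:, None]
    walk = np.cumsum(steps, axis=1)
    hi = walk.max(axis=1)
    lo = walk.min(axis=1)
    return np.where(np.abs(hi) >= np.abs(lo), hi, lo)


def _perm_pvalue(es: float, perm: np.ndarray) -> float:
    """One-sided permutation p on the sign of the observed ES, normalized by
    the permutations of matching sign (the fgsea convention), with the +1
    correction; this keeps null p-values approximately uniform."""
    matching = np.sign(perm) == np.sign(es) if es != 0 else np.ones_like(perm, dtype=bool)
    extreme = int(np.sum(matching & (np.abs(perm) >= abs(es))))
    return (1 + extreme) / (1 + int(matching.sum()))


def preranked_gsea(
    rl: RankedList,
    gene_set,
    n_perm: int = 10_000,
    weight: float = 1.0,
    seed: int | np.random.Generator = 0,
    min_set_size: int = 5,
) -> GseaResult | SkippedRecord:
    """Weighted KS enrichment of ``gene_set`` in the ranked list.

    The permutation null redraws the set as a size-matched random subset of
    gene labels; the p-value is one-sided on the sign of the observed ES with
    the +1 small-sample correction.  ``fdr`` is filled by
    :func:`score_and_select` across the tested miRNAs (NaN here).
    """
    members = set(gene_set)
    hit_mask = np.array([g in members for g in rl.gene_ids])
    n_hit = int(hit_mask.sum())
    if n_hit < min_set_size:
        return SkippedRecord(rl.mirna_id, f"only {n_hit} set genes in list (< {min_set_size})")
    if n_hit == len(rl.gene_ids):
        return SkippedRecord(rl.mirna_id, "gene set covers the entire list")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    es = enrichment_score(rl.rank_values, hit_mask, weight)
    perm = _permutation_es(rl.rank_values, n_hit, weight, n_perm, rng)
    p = _perm_pvalue(es, perm)
    return GseaResult(es=es, p_perm=p, fdr=float("nan"), n_perm=n_perm, p_raw=p)


def score_and_select(
    results: list[tuple[str, GseaResult]],
    tes_threshold: float = 0.995,
    fdr_threshold: float = 0.05,
    tes_p: str = "adjusted",
) -> list[ModulatorRecord]:
    """BH-correct permutation p-values across miRNAs, form TES, flag modulators.

    TES = (1 - 2p) * sign(ES) with p the BH-adjusted permutation p by default
    (``tes_p="raw"`` switches to the raw permutation p).  A miRNA is flagged
    iff |TES| > tes_threshold and FDR < fdr_threshold (both strict).
    """
    if not results:
        return []
    if tes_p not in ("adjusted", "raw"):
        raise ValueError("tes_p must be 'adjusted' or 'raw'")
    raw = np.array([r.p_raw if r.p_raw is not None else r.p_perm for _, r in results])
    fdr = multipletests(raw, method="fdr_bh")[1]
    out = []
    for (mid, res), p_adj, p_r in zip(results, fdr, raw):
        res.fdr = float(p_adj)
        p_use = p_adj if tes_p == "adjusted" else p_r
        tes = float((1.0 - 2.0 * p_use) * np.sign(res.es))
        flag = abs(tes) > tes_threshold and res.fdr < fdr_threshold
        out.append(ModulatorRecord(mid, res, tes, bool(flag)))
    return out


def modulator_scan(
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    purity: PurityVector,
    gene_set,
    n_perm: int = 10_000,
    weight: float = 1.0,
    seed: int = 0,
    tes_threshold: float = 0.995,
    fdr_threshold: float = 0.05,
    min_set_size: int = 5,
    p_method: str = "ratio",
    tes_p: str = "adjusted",
) -> tuple[list[ModulatorRecord], list[SkippedRecord]]:
    """Run the full three-step scan for every miRNA against one gene set."""
    if mirna.sample_ids != mrna.sample_ids:
        raise ValueError("miRNA and mRNA matrices must share sample ids in order")
    pvec = purity.aligned_to(mirna.sample_ids)
    _, _, _, _, _, ri = _association_table(mirna.values, mrna.values, pvec, p_method)
    genes = np.array(mrna.feature_ids)
    members = set(gene_set)
    member_mask_by_gene = np.array([g in members for g in genes])

    rng = np.random.default_rng(seed)
    tested: list[tuple[str, GseaResult]] = []
    skipped: list[SkippedRecord] = []
    for i, mid in enumerate(mirna.feature_ids):
        order = np.lexsort((genes, -ri[i]))
        rl = RankedList(mid, [str(g) for g in genes[order]], ri[i][order])
        # reuse precomputed membership to avoid re-hashing per miRNA
        hit_mask = member_mask_by_gene[order]
        n_hit = int(hit_mask.sum())
        if n_hit < min_set_size:
            skipped.append(SkippedRecord(mid, f"only {n_hit} set genes in list (< {min_set_size})"))
            continue
        if n_hit == len(genes):
            skipped.append(SkippedRecord(mid, "gene set covers the entire list"))
            continue
        es = enrichment_score(rl.rank_values, hit_mask, weight)
        perm = _permutation_es(rl.rank_values, n_hit, weight, n_perm, rng)
        p = _perm_pvalue(es, perm)
        tested.append((mid, GseaResult(es=es, p_perm=p, fdr=float("nan"), n_perm=n_perm, p_raw=p)))
    records = score_and_select(tested, tes_threshold, fdr_threshold, tes_p)
    return records, skipped
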