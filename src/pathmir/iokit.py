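"""Readers, writers and preprocessing for expression matrices, gene sets,
survival tables and tumor-purity vectors.

Expression matrices live on disk as TSV/CSV with features in rows (first
column = feature id) and a header row of sample ids.  Gene sets use the GMT
convention (name, description, members, tab-separated).  Survival tables are
CSV with columns ``sample_id, time, event`` followed by optional covariates.
Purity is a two-column CSV (``sample_id, purity``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

VALID_UNITS = ("count", "TPM", "RPM", "array_intensity", "zscore")


class ParseError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class ExpressionMatrix:
    """A features x samples numeric matrix with a unit tag.

    ``data`` is a pandas DataFrame indexed by feature id with sample ids as
    columns.  Ids must be unique, values finite; ``count`` matrices must be
    non-negative and integral.
    """

    data: pd.DataFrame
    unit_tag: str = "count"

    def __post_init__(self) -> None:
        if self.unit_tag not in VALID_UNITS:
            raise ValueError(f"unknown unit_tag {self.unit_tag!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate feature ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ParseError(
                f"non-finite value at feature {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )
        if self.unit_tag == "count":
            if (values < 0).any():
                raise ParseError("count matrix contains negative values")
            if not np.allclose(values, np.round(values)):
                raise ParseError("count matrix contains non-integral values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_features(self, ids) -> "ExpressionMatrix":
        missing = [i for i in ids if i not in self.data.index]
        if missing:
            raise KeyError(f"features not present: {missing}")
        return ExpressionMatrix(self.data.loc[list(ids)], self.unit_tag)

    def subset_samples(self, ids) -> "ExpressionMatrix":
        missing = [i for i in ids if i not in self.data.columns]
        if missing:
            raise KeyError(f"samples not present: {missing}")
        return ExpressionMatrix(self.data[list(ids)], self.unit_tag)


@dataclass
class SurvivalTable:
    """Per-sample follow-up time, event indicator and optional covariates."""

    data: pd.DataFrame  # index = sample_id; columns: time, event, covariates...

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ParseError("duplicate sample ids in survival table")
        if not {"time", "event"}.issubset(self.data.columns):
            raise ParseError("survival table needs 'time' and 'event' columns")
        if (self.data["time"] <= 0).any():
            bad = self.data.index[self.data["time"] <= 0].tolist()
            raise ParseError(f"non-positive follow-up time for samples {bad}")
        ev = set(self.data["event"].unique())
        if not ev.issubset({0, 1}):
            raise ParseError(f"event indicator must be 0/1, found {sorted(ev)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())

    @property
    def covariates(self) -> pd.DataFrame:
        return self.data.drop(columns=["time", "event"])

    def subset(self, ids) -> "SurvivalTable":
        return SurvivalTable(self.data.loc[list(ids)])


@dataclass
class GeneSetCollection:
    """Named gene sets; duplicate members within a set are collapsed."""

    sets: dict[str, list[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        cleaned = {}
        for name, members in self.sets.items():
            uniq = list(dict.fromkeys(str(m) for m in members))
            if not uniq:
                raise ParseError(f"gene set {name!r} is empty")
            cleaned[name] = uniq
        self.sets = cleaned

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class PurityVector:
    """Tumor purity (malignant-cell fraction) per sample, in [0, 1]."""

    values: pd.Series  # index = sample_id

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ParseError("duplicate sample ids in purity vector")
        v = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            raise ParseError("non-finite purity value")
        if (v < 0).any() or (v > 1).any():
            raise ParseError("purity values must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def aligned_to(self, sample_ids) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.values.index]
        if missing:
            raise KeyError(f"purity missing for samples: {missing}")
        return self.values.loc[list(sample_ids)].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path, format: str = "tsv", unit_tag: str = "count") -> ExpressionMatrix:
    """Read a features x samples matrix; first column feature ids, header sample ids."""
    sep = {"tsv": "\t", "csv": ","}.get(format)
    if sep is None:
        raise ValueError(f"format must be 'tsv' or 'csv', got {format!r}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        col = df.columns[df.isna().any(axis=0)][0]
        raise ParseError(f"missing/non-numeric value near feature {row!r}, sample {col!r} in {path}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
            raise ParseError(f"non-numeric cell(s) in sample column {col!r}, feature(s) {bad}")
    return ExpressionMatrix(df, unit_tag)


def write_expression(m: ExpressionMatrix, path, format: str = "tsv") -> None:
    sep = {"tsv": "\t", "csv": ","}[format]
    m.data.to_csv(path, sep=sep)


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{ln}: GMT line needs name, description, >=1 member")
            name = parts[0]
            if name in sets:
                raise ParseError(f"{path}:{ln}: duplicate gene set name {name!r}")
            members = [g for g in parts[2:] if g]
            if not members:
                raise ParseError(f"{path}:{ln}: gene set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets, provenance=str(path))


def write_gmt(sets: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def read_survival(path) -> SurvivalTable:
    df = pd.read_csv(path)
    if df.columns[0] != "sample_id":
        raise ParseError("survival CSV must start with a 'sample_id' column")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return SurvivalTable(df)


def write_survival(surv: SurvivalTable, path) -> None:
    surv.data.rename_axis("sample_id").to_csv(path)


def read_purity(path) -> PurityVector:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["sample_id", "purity"]:
        raise ParseError("purity CSV must have columns sample_id, purity")
    s = df.set_index("sample_id")["purity"]
    s.index = s.index.astype(str)
    return PurityVector(s)


def write_purity(p: PurityVector, path) -> None:
    p.values.rename("purity").rename_axis("sample_id").to_csv(path)


# ---------------------------------------------------------------------------
# preprocessing


def normalize_counts(m: ExpressionMatrix, mode: str, lengths: dict[str, float] | None = None) -> ExpressionMatrix:
    """Library-size normalization of a count matrix.

    ``rpm``: counts scaled to reads per million within each sample.
    ``tpm``: counts are first divided by feature length in bases, then each
    sample's rates are rescaled to sum to 1e6 (so TPM columns sum to 1e6).
    """
    if m.unit_tag != "count":
        raise ValueError(f"normalize_counts expects counts, got {m.unit_tag}")
    values = m.values
    colsums = values.sum(axis=0)
    if (colsums == 0).any():
        bad = [m.sample_ids[i] for i in np.flatnonzero(colsums == 0)]
        raise ValueError(f"zero column sum for sample(s) {bad}")
    if mode == "rpm":
        out = values * 1e6 / colsums
        tag = "RPM"
    elif mode == "tpm":
        if lengths is None:
            raise ValueError("tpm normalization requires feature lengths")
        missing = [f for f in m.feature_ids if f not in lengths]
        if missing:
            raise ValueError(f"missing length for feature(s) {missing}")
        lens = np.array([lengths[f] for f in m.feature_ids], dtype=float)
        if (lens <= 0).any():
            raise ValueError("feature lengths must be positive")
        rate = values / lens[:, None]
        out = rate * 1e6 / rate.sum(axis=0)
        tag = "TPM"
    else:
        raise ValueError(f"mode must be 'tpm' or 'rpm', got {mode!r}")
    return ExpressionMatrix(pd.DataFrame(out, index=m.feature_ids, columns=m.sample_ids), tag)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common reference distribution.

    The reference is the across-sample mean of within-sample sorted values;
    tied values within a sample receive the mean of the reference values at
    the rank positions they span.
    """
    if m.n_samples < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    values = m.values
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = sorted_vals.mean(axis=1)

    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        idx = order[:, j]
        assigned = np.empty_like(reference)
        assigned[idx] = reference
        # collapse ties: every position sharing a value gets the mean of the
        # reference values its tied block spans
        uniq, inv = np.unique(col, return_inverse=True)
        sums = np.bincount(inv, weights=assigned)
        counts = np.bincount(inv)
        out[:, j] = (sums / counts)[inv]
    tag = m.unit_tag if m.unit_tag != "count" else "array_intensity"
    return ExpressionMatrix(pd.DataFrame(out, index=m.feature_ids, columns=m.sample_ids), tag)


def filter_low_expression(m: ExpressionMatrix, max_zero_fraction: float = 0.5) -> ExpressionMatrix:
    """Drop features whose zero fraction strictly exceeds ``max_zero_fraction``."""
    frac = (m.values == 0).mean(axis=1)
    keep = frac <= max_zero_fraction
    if not keep.any():
        warnings.warn("all features removed by low-expression filter")
    return ExpressionMatrix(m.data.loc[keep], m.unit_tag)


def harmonize_cohorts(cohorts: list[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Restrict all cohorts to their shared features, in lexicographic order."""
    if len(cohorts) < 2:
        raise ValueError("harmonize_cohorts needs >= 2 cohorts")
    shared = set(cohorts[0].feature_ids)
    for c in cohorts[1:]:
        shared &= set(c.feature_ids)
    if not shared:
        raise ValueError("cohorts share no features")
    order = sorted(shared)
    return [c.subset_features(order) for c in cohorts]


def zscore_by_feature(m: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each feature to mean 0, sample standard deviation 1 (ddof=1)."""
    values = m.values
    sd = values.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = [m.feature_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance feature(s): {bad}")
    out = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    return ExpressionMatrix(pd.DataFrame(out, index=m.feature_ids, columns=m.sample_ids), "zscore")
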