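"""Typed I/O for expression matrices, clinical tables and gene sets.

This module defines the shared data model used by every analysis stage:

* :class:`ExpressionMatrix` — a gene-by-sample numeric matrix with an
  explicit unit tag (raw counts vs log2-normalized values), because the
  downstream stages care about the difference (differential expression
  needs counts, z-scoring needs log-scale values).
* :class:`ClinicalTable` — per-sample condition, survival endpoints and
  the clinical covariates used for Cox adjustment (age, PSA, Gleason
  group, TNM group) plus optional PAM50/PCS subtype labels.
* :class:`GeneSetCollection` — named gene sets read from GMT files; the
  union of members forms the candidate gene universe.

All tables are tab-separated UTF-8 with a header row, matching common
TCGA-derived exports.  Gene and sample matching is exact string match;
symbol-alias resolution is an upstream concern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionUnit",
    "ExpressionMatrix",
    "ClinicalTable",
    "GeneSetCollection",
    "AlignedCohort",
    "CohortIOError",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_gmt",
    "align_cohort",
]

#: sentinel strings treated as missing in clinical tables
NA_STRINGS = ("", "NA", "NaN", "nan", "na")


class CohortIOError(ValueError):
    """Raised for malformed or invariant-violating input files."""


class ExpressionUnit(str, Enum):
    """Unit tag for an expression matrix."""

    raw_counts = "raw_counts"
    log2_normalized = "log2_normalized"


@dataclass
class ExpressionMatrix:
    """Gene-by-sample numeric expression matrix.

    Parameters
    ----------
    gene_ids : list of str
        Unique row identifiers.
    sample_ids : list of str
        Unique column identifiers.
    values : ndarray of shape (n_genes, n_samples)
        Expression values; non-negative and finite when ``unit`` is
        ``raw_counts``.
    unit : ExpressionUnit
        Whether values are raw counts or log2-normalized expression.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    unit: ExpressionUnit = ExpressionUnit.raw_counts

    def __post_init__(self) -> None:
        self.unit = ExpressionUnit(self.unit)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise CohortIOError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise CohortIOError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise CohortIOError(f"duplicate gene id: {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise CohortIOError(f"duplicate sample id: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            raise CohortIOError("expression matrix contains non-finite values")
        if self.unit is ExpressionUnit.raw_counts and np.any(self.values < 0):
            raise CohortIOError("raw count matrix contains negative values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        """Return a genes x samples DataFrame view."""
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` (all must be present), preserving their order."""
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids),
                                self.values[rows, :], self.unit)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``samples`` (all must be present), preserving their order."""
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in idx]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        cols = [idx[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), list(samples),
                                self.values[:, cols], self.unit)

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene), :]


def read_expression(path: str | Path, unit: ExpressionUnit | str) -> ExpressionMatrix:
    """Read a gene-by-sample TSV (first column gene ids, header sample ids).

    Raises
    ------
    CohortIOError
        On ragged rows, non-numeric cells, duplicate gene/sample ids, or
        negative values when ``unit`` is ``raw_counts``.
    """
    unit = ExpressionUnit(unit)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dup = _first_duplicate(header[1:])
    if dup:
        raise CohortIOError(f"duplicate sample id in header: {dup!r}")
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise CohortIOError(f"malformed expression TSV {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise CohortIOError(f"expression TSV {path} has no sample columns")
    if df.isna().any().any():
        raise CohortIOError(f"expression TSV {path} has missing/ragged cells")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise CohortIOError(f"non-numeric cell in expression TSV {path}: {exc}") from exc
    return ExpressionMatrix(list(df.index.astype(str)), list(df.columns.astype(str)),
                            values, unit)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV; round-trips bit-exactly through repr floats."""
    df = expr.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------

#: canonical clinical column names (optional ones may be absent from file)
CLINICAL_REQUIRED = ["sample_id", "condition"]
CLINICAL_OPTIONAL = [
    "os_time", "os_event", "pfs_time", "pfs_event",
    "age", "psa", "gleason", "gleason_group", "tnm_group", "pam50", "pcs",
]

_GLEASON_GROUPS = {"le7", "gt7"}
_TNM_GROUPS = {"early", "other"}
_PAM50 = {"LumA", "LumB", "Basal"}
_PCS = {"PCS1", "PCS2", "PCS3"}


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates and survival endpoints.

    Stored as a DataFrame indexed by ``sample_id`` with columns
    ``condition`` ('tumor'/'normal'), ``os_time``/``os_event``,
    ``pfs_time``/``pfs_event``, ``age``, ``psa``, ``gleason_group``
    ('le7'/'gt7'), ``tnm_group`` ('early'/'other'; early = T1/T2 N0 M0)
    and optional ``pam50``/``pcs`` labels.  Missing values are NaN/None;
    rows with missing survival fields are retained and flagged, never
    silently dropped.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise CohortIOError(f"duplicate sample_id: {dup!r}")
        for col in ("os_event", "pfs_event"):
            vals = df[col].dropna()
            bad = vals[~vals.isin([0.0, 1.0])]
            if len(bad):
                raise CohortIOError(
                    f"{col} must be 0/1; got {bad.iloc[0]!r} for sample {bad.index[0]!r}")
        for col in ("os_time", "pfs_time"):
            vals = df[col].dropna()
            if (vals < 0).any():
                s = vals[vals < 0].index[0]
                raise CohortIOError(f"negative {col} for sample {s!r}")
        bad_cond = df["condition"][~df["condition"].isin(["tumor", "normal"])]
        if len(bad_cond):
            raise CohortIOError(
                f"unknown condition {bad_cond.iloc[0]!r} for sample {bad_cond.index[0]!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def n_samples(self) -> int:
        return len(self.df)

    def tumor_ids(self) -> list[str]:
        return list(self.df.index[self.df["condition"] == "tumor"])

    def condition_labels(self, sample_ids: Sequence[str]) -> np.ndarray:
        return self.df.loc[list(sample_ids), "condition"].to_numpy()

    def survival(self, endpoint: str, sample_ids: Sequence[str] | None = None,
                 ) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Return (times, events, used_ids) for ``endpoint`` in {'os','pfs'}.

        Samples with missing time or event flag are excluded with a warning,
        per the complete-case policy for survival operations.
        """
        endpoint = endpoint.lower()
        if endpoint not in ("os", "pfs"):
            raise ValueError(f"endpoint must be 'os' or 'pfs', got {endpoint!r}")
        ids = list(sample_ids) if sample_ids is not None else self.tumor_ids()
        sub = self.df.loc[ids]
        t, e = sub[f"{endpoint}_time"], sub[f"{endpoint}_event"]
        ok = t.notna() & e.notna()
        n_dropped = int((~ok).sum())
        if n_dropped:
            warnings.warn(
                f"{n_dropped} sample(s) missing {endpoint} survival fields "
                "excluded from survival analysis", stacklevel=2)
        used = list(sub.index[ok])
        return (t[ok].to_numpy(float), e[ok].to_numpy(float), used)

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.df.loc[list(sample_ids)].copy())


def _gleason_group(raw: str) -> str:
    """Map a raw Gleason score or group code to 'le7'/'gt7'."""
    if raw in _GLEASON_GROUPS:
        return raw
    try:
        score = float(raw)
    except ValueError:
        raise CohortIOError(f"unknown Gleason code {raw!r}") from None
    return "gt7" if score > 7 else "le7"


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a per-sample clinical TSV.

    Expected columns: ``sample_id``, ``condition`` and any of the
    documented optional columns; a raw ``gleason`` score column is
    dichotomized to ``gleason_group`` at the conventional <=7 vs >7 cut.
    Missing optional columns yield all-missing columns.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in CLINICAL_REQUIRED:
        if col not in raw.columns:
            raise CohortIOError(f"clinical table missing required column {col!r}")
    unknown = set(raw.columns) - set(CLINICAL_REQUIRED) - set(CLINICAL_OPTIONAL)
    if unknown:
        raise CohortIOError(f"unknown clinical columns: {sorted(unknown)}")
    raw = raw.replace(list(NA_STRINGS), np.nan)
    if raw["sample_id"].isna().any():
        raise CohortIOError("clinical table has empty sample_id cells")

    out = pd.DataFrame(index=pd.Index(raw["sample_id"].astype(str), name="sample_id"))
    out["condition"] = raw["condition"].to_numpy()
    for col in ("os_time", "os_event", "pfs_time", "pfs_event", "age", "psa"):
        if col in raw.columns:
            try:
                out[col] = pd.to_numeric(raw[col]).to_numpy()
            except (ValueError, TypeError) as exc:
                raise CohortIOError(f"non-numeric value in column {col!r}: {exc}") from exc
        else:
            out[col] = np.nan

    if "gleason_group" in raw.columns:
        gg = raw["gleason_group"]
        bad = gg.dropna()[~gg.dropna().isin(_GLEASON_GROUPS)]
        if len(bad):
            raise CohortIOError(f"unknown gleason_group {bad.iloc[0]!r}")
        out["gleason_group"] = gg.to_numpy()
    elif "gleason" in raw.columns:
        out["gleason_group"] = [
            _gleason_group(v) if isinstance(v, str) else np.nan for v in raw["gleason"]]
    else:
        out["gleason_group"] = np.nan

    if "tnm_group" in raw.columns:
        tg = raw["tnm_group"]
        bad = tg.dropna()[~tg.dropna().isin(_TNM_GROUPS)]
        if len(bad):
            raise CohortIOError(f"unknown tnm_group {bad.iloc[0]!r} "
                                "(expected 'early' = T1/T2N0M0 or 'other')")
        out["tnm_group"] = tg.to_numpy()
    else:
        out["tnm_group"] = np.nan

    for col, allowed in (("pam50", _PAM50), ("pcs", _PCS)):
        if col in raw.columns:
            vals = raw[col]
            bad = vals.dropna()[~vals.dropna().isin(allowed)]
            if len(bad):
                raise CohortIOError(f"unknown {col} label {bad.iloc[0]!r}")
            out[col] = vals.to_numpy()
        else:
            out[col] = np.nan

    return ClinicalTable(out)


def write_clinical(clin: ClinicalTable, path: str | Path) -> None:
    clin.df.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets; the union of members is the candidate universe."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sets:
            raise CohortIOError("gene set collection is empty")

    @property
    def set_names(self) -> list[str]:
        return list(self.sets)

    def union(self) -> list[str]:
        """All member genes, deduplicated, in first-appearance order."""
        seen: dict[str, None] = {}
        for members in self.sets.values():
            for g in members:
                seen.setdefault(g, None)
        return list(seen)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file: name <tab> description <tab> members..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CohortIOError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
            name, desc, *members = fields
            if name in sets:
                raise CohortIOError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = [m for m in members if m]
            # within-set duplicates are collapsed, keeping order
            sets[name] = list(dict.fromkeys(members))
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignedCohort:
    """Expression restricted to candidate genes, samples intersected with clinical.

    ``dropped_genes`` lists candidate genes absent from the expression
    matrix, so that ``len(dropped_genes) + expression.n_genes`` equals the
    candidate-universe size.
    """

    expression: ExpressionMatrix
    clinical: ClinicalTable
    dropped_genes: list[str]
    dropped_samples: list[str]

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids


def align_cohort(expr: ExpressionMatrix, clin: ClinicalTable,
                 genes: GeneSetCollection | Sequence[str]) -> AlignedCohort:
    """Intersect an expression matrix with clinical rows and candidate genes.

    Candidate genes absent from the matrix are reported as dropped (never an
    error — curated pathway lists routinely contain symbols missing from a
    given expression platform).  Sample order of the expression and clinical
    views is identical in the result.
    """
    universe = genes.union() if isinstance(genes, GeneSetCollection) else list(genes)
    present = set(expr.gene_ids)
    kept = [g for g in universe if g in present]
    dropped = [g for g in universe if g not in present]
    if not kept:
        raise CohortIOError("no candidate gene present in the expression matrix")

    clin_ids = set(clin.sample_ids)
    shared = [s for s in expr.sample_ids if s in clin_ids]
    dropped_samples = sorted((set(expr.sample_ids) | clin_ids) - set(shared))
    if not shared:
        raise CohortIOError("expression and clinical tables share no sample ids")

    sub_expr = expr.subset_genes(kept).subset_samples(shared)
    sub_clin = clin.subset(shared)
    return AlignedCohort(sub_expr, sub_clin, dropped, dropped_samples)


def _first_duplicate(items: Iterable[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""
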