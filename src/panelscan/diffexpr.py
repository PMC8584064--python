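"""Tumor-vs-normal differential expression and the SDE candidate filter.

The DE engine is a negative-binomial Wald test on raw counts:

1. median-of-ratios size factors (geometric-mean reference);
2. per-gene method-of-moments NB dispersion on normalized counts,
   pooled within condition groups;
3. log2 fold change from normalized group means with a 0.5 pseudocount;
4. Wald z = log2FC / SE(log2FC) with a delta-method SE, two-sided
   normal p-value;
5. Benjamini–Hochberg adjustment across genes.

This is deliberately simpler than DESeq2 (no dispersion shrinkage,
Cox–Reid adjustment or outlier refitting): the candidate filter sits
downstream of whichever DE engine produced the table, so the pipeline
also accepts a precomputed DE table (e.g. DESeq2 output) with the same
columns via :func:`read_de_table`.

A gene is a significantly differentially expressed (SDE) candidate when
``|log2FC| > lfc_threshold`` (strict) and its adjusted p-value is below
``p_threshold`` (strict); each candidate carries the sign of its log2FC,
which later orients the gene in the panel score (down-regulated genes
are sign-flipped).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort_io import ExpressionMatrix, ExpressionUnit

__all__ = [
    "DEResult",
    "size_factors",
    "test_gene_de",
    "adjust_bh",
    "select_sde",
    "run_de",
    "read_de_table",
    "write_de_table",
]

DE_COLUMNS = ["gene_id", "base_mean", "log2FC", "p_raw", "p_adj", "sde", "sign"]

#: pseudocount added to normalized group means before the log2 ratio
PSEUDOCOUNT = 0.5
#: floor for the method-of-moments dispersion estimate
MIN_DISPERSION = 1e-8


@dataclass
class DEResult:
    """Per-gene differential expression call."""

    gene_id: str
    base_mean: float
    log2fc: float
    p_raw: float
    p_adj: float = np.nan
    sde: bool = False

    @property
    def sign(self) -> int:
        """Direction of regulation: +1 up in tumor, -1 down (0 if no change)."""
        return int(np.sign(self.log2fc))


def size_factors(expr: ExpressionMatrix) -> np.ndarray:
    """Median-of-ratios size factors (DESeq-style normalization).

    The reference is the per-gene geometric mean over samples; each
    sample's factor is the median of its count/reference ratios over
    genes whose reference is positive (i.e. genes with no zero count).
    """
    if expr.unit is not ExpressionUnit.raw_counts:
        raise ValueError("size factors require raw counts")
    counts = expr.values
    if not counts.any():
        raise ValueError("all-zero count matrix")
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts)
    # geometric mean is 0 for any gene containing a zero -> excluded
    log_ref = log_counts.mean(axis=1)
    usable = np.isfinite(log_ref)
    if not usable.any():
        raise ValueError("every gene has a zero count; cannot form reference")
    ratios = log_counts[usable, :] - log_ref[usable, None]
    factors = np.exp(np.median(ratios, axis=0))
    if np.any(factors <= 0) or not np.all(np.isfinite(factors)):
        raise ValueError("non-positive size factor; check for empty samples")
    return factors


def _mom_dispersion(norm: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Method-of-moments NB dispersion per gene, pooled within groups.

    For NB, Var = mu + alpha * mu^2, so alpha = (s^2 - mu)/mu^2 estimated
    within each condition (to avoid counting the group-mean difference as
    dispersion) and pooled by residual degrees of freedom.
    """
    n_genes = norm.shape[0]
    num = np.zeros(n_genes)
    den = 0.0
    mu_all = np.zeros(n_genes)
    w_all = 0.0
    for idx in groups:
        sub = norm[:, idx]
        k = sub.shape[1]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        num += (k - 1) * (var - mu)
        den += k - 1
        mu_all += k * mu
        w_all += k
    mu_all /= w_all
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (num / den) / mu_all ** 2
    alpha[~np.isfinite(alpha)] = MIN_DISPERSION
    return np.clip(alpha, MIN_DISPERSION, None)


def test_gene_de(expr: ExpressionMatrix, condition: Sequence[str],
                 factors: np.ndarray | None = None) -> list[DEResult]:
    """NB Wald test per gene for tumor vs normal (without the SDE flag).

    ``condition`` holds per-sample labels 'tumor'/'normal' in matrix
    column order; both groups need at least two samples.  All-zero genes
    produce the defined degenerate output (log2FC 0, p 1) rather than
    being dropped, so every input gene appears in the result.
    """
    cond = np.asarray([str(c) for c in condition])
    if cond.shape[0] != expr.n_samples:
        raise ValueError("condition length does not match sample count")
    tumor = np.where(cond == "tumor")[0]
    normal = np.where(cond == "normal")[0]
    if tumor.size < 2 or normal.size < 2:
        raise ValueError("each condition needs at least 2 samples")
    if factors is None:
        factors = size_factors(expr)
    norm = expr.values / factors[None, :]

    alpha = _mom_dispersion(norm, [tumor, normal])
    mu_t = norm[:, tumor].mean(axis=1)
    mu_n = norm[:, normal].mean(axis=1)
    base_mean = norm.mean(axis=1)

    log2fc = np.log2((mu_t + PSEUDOCOUNT) / (mu_n + PSEUDOCOUNT))

    # delta method on log2 of the pseudocounted means:
    # Var(log2 mu_hat) ~= Var(mu_hat) / (ln2 * (mu + c))^2, with NB
    # Var(mu_hat_g) = mean_i(mu + alpha mu^2 adjusted for size factor) / k
    ln2 = np.log(2.0)
    var_t = _group_mean_var(mu_t, alpha, factors[tumor])
    var_n = _group_mean_var(mu_n, alpha, factors[normal])
    se2 = (var_t / (mu_t + PSEUDOCOUNT) ** 2 + var_n / (mu_n + PSEUDOCOUNT) ** 2) / ln2 ** 2
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    all_zero = expr.values.sum(axis=1) == 0
    log2fc[all_zero] = 0.0
    p[all_zero] = 1.0
    p[~np.isfinite(p)] = 1.0

    return [DEResult(g, float(base_mean[i]), float(log2fc[i]), float(p[i]))
            for i, g in enumerate(expr.gene_ids)]


def _group_mean_var(mu: np.ndarray, alpha: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Variance of a normalized-count group mean under NB sampling.

    A raw count K_i ~ NB(mean f_i * mu, dispersion alpha); the normalized
    value K_i / f_i then has variance mu/f_i + alpha*mu^2, averaged over
    the group and divided by the group size.
    """
    k = f.size
    per_sample = mu[:, None] / f[None, :] + alpha[:, None] * mu[:, None] ** 2
    return per_sample.mean(axis=1) / k


def adjust_bh(p_raw: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_sde(results: Sequence[DEResult], lfc_threshold: float = 1.0,
               p_threshold: float = 0.05, use_adjusted: bool = True,
               ) -> list[DEResult]:
    """Apply the SDE filter and return the selected candidates.

    Selection is ``|log2FC| > lfc_threshold`` and p below ``p_threshold``,
    both strict.  ``use_adjusted`` switches between the BH-adjusted
    (default) and raw p-value; adjusted p-values are computed here if any
    are missing.  Results are returned in input gene order regardless of
    how the input was sorted; the ``sde`` flag is set on every input row.
    """
    results = list(results)
    if not results:
        return []
    p_adj = np.array([r.p_adj for r in results])
    if np.any(np.isnan(p_adj)):
        p_adj = adjust_bh([r.p_raw for r in results])
    selected = []
    for r, pa in zip(results, p_adj):
        r.p_adj = float(pa)
        p_use = r.p_adj if use_adjusted else r.p_raw
        r.sde = bool(abs(r.log2fc) > lfc_threshold and p_use < p_threshold)
        if r.sde:
            selected.append(r)
    return selected


def run_de(expr: ExpressionMatrix, condition: Sequence[str],
           lfc_threshold: float = 1.0, p_threshold: float = 0.05,
           use_adjusted: bool = True) -> tuple[list[DEResult], list[DEResult]]:
    """Full DE stage: size factors, per-gene NB Wald, BH, SDE filter.

    Returns (all results, selected SDE candidates).
    """
    results = test_gene_de(expr, condition)
    selected = select_sde(results, lfc_threshold, p_threshold, use_adjusted)
    return results, selected


# ---------------------------------------------------------------------------
# DE table I/O (also the entry point for external engines such as DESeq2)
# ---------------------------------------------------------------------------

def to_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame({
        "gene_id": [r.gene_id for r in results],
        "base_mean": [r.base_mean for r in results],
        "log2FC": [r.log2fc for r in results],
        "p_raw": [r.p_raw for r in results],
        "p_adj": [r.p_adj for r in results],
        "sde": [r.sde for r in results],
        "sign": [r.sign for r in results],
    })


def write_de_table(results: Sequence[DEResult], path: str | Path) -> None:
    to_frame(results).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_de_table(path: str | Path) -> list[DEResult]:
    """Read a DE table (own output or an external engine's export).

    Required columns: gene_id, log2FC and at least one of p_raw / p_adj.
    Missing p_raw defaults to p_adj (conservative for raw-p filtering).
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "log2FC"):
        if col not in df.columns:
            raise ValueError(f"DE table missing column {col!r}")
    if "p_raw" not in df.columns and "p_adj" not in df.columns:
        raise ValueError("DE table needs a p_raw or p_adj column")
    out = []
    for _, row in df.iterrows():
        p_adj = float(row["p_adj"]) if "p_adj" in df.columns else np.nan
        p_raw = float(row["p_raw"]) if "p_raw" in df.columns else p_adj
        out.append(DEResult(str(row["gene_id"]),
                            float(row.get("base_mean", np.nan)),
                            float(row["log2FC"]), p_raw, p_adj))
    return out
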