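"""Additive-effect analysis: exhaustive median-split survival screening.

The screening procedure that selects the prognostic panel:

1. each candidate gene's (log-scale) expression is z-scored across the
   scored tumor cohort, then multiplied by the gene's direction sign
   (+1 for genes up-regulated in tumors, -1 for down-regulated ones, so
   that higher always means "more tumor-like");
2. for every non-empty subset of the k candidates (2^k - 1 subsets) the
   multi-gene score is the per-sample sum of the signed z-scores;
3. samples are split at the sample median of the score ("higher" =
   strictly above the cutoff);
4. the two groups are compared by the log-rank test, and subsets are
   ranked — by lowest p-value with a highest-HR then smallest-subset
   tie-break by default, or by highest HR.

The full ranking is always returned, never just the winner, together
with the number of subsets screened: with 255 correlated tests and no
multiplicity correction the winner's unadjusted p-value is
anti-conservative, and reports should carry the screen size (a
Bonferroni reference line is included as documentation).

The z-scoring population is exactly the scored cohort: adding unscored
(e.g. normal) samples to the matrix does not change any result.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_io import ClinicalTable, ExpressionMatrix
from .survival_core import (KMCurve, LogRankResult, SurvivalError, km_estimate,
                            logrank_test)

__all__ = [
    "PanelDefinition",
    "ScoreVector",
    "CombinationRanking",
    "zscore_transform",
    "multigene_score",
    "median_split",
    "additive_search",
    "evaluate_panel",
]

#: exhaustive enumeration refuses more candidates than this (2^20 - 1 subsets)
MAX_CANDIDATES = 20


@dataclass
class PanelDefinition:
    """An ordered gene panel with per-gene direction signs."""

    genes: list[str]
    signs: list[int]

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.signs):
            raise ValueError("genes and signs must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("panel genes must be unique")
        if any(s not in (1, -1) for s in self.signs):
            raise ValueError("signs must be +1 or -1")


@dataclass
class ScoreVector:
    """Per-sample multi-gene score with its median split."""

    sample_ids: list[str]
    scores: np.ndarray
    median_cutoff: float | None = None
    groups: np.ndarray | None = None   # 'higher' / 'lower'

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.sample_ids, name="score")


@dataclass
class CombinationRanking:
    """Every screened subset with its log-rank statistics, ranked.

    ``table`` columns: subset (comma-joined genes), size, logrank_p, hr,
    ci_low, ci_high, chi2, status.  Degenerate subsets (split or test
    failed) carry a failure reason in ``status`` and rank last.
    """

    table: pd.DataFrame
    criterion: str
    n_screened: int
    endpoint: str
    bonferroni_alpha: float = field(default=np.nan)

    @property
    def selected(self) -> list[str]:
        """Genes of the top-ranked subset."""
        return self.table.iloc[0]["subset"].split(",")


def zscore_transform(expr: ExpressionMatrix, genes: Sequence[str],
                     signs: Sequence[int]) -> pd.DataFrame:
    """Per-gene z-score across the scored samples, then sign application.

    Returns a genes x samples DataFrame whose rows (before the sign flip)
    have mean 0 and unit standard deviation.  A zero-variance gene cannot
    be z-scored and raises, naming the gene.
    """
    if len(genes) != len(signs):
        raise ValueError("genes and signs length mismatch")
    sub = expr.subset_genes(list(genes))
    vals = sub.values
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    flat = np.where(sd[:, 0] == 0)[0]
    if flat.size:
        raise ValueError(f"zero-variance gene cannot be z-scored: {genes[flat[0]]!r}")
    z = (vals - mean) / sd
    z *= np.asarray(signs, dtype=float)[:, None]
    return pd.DataFrame(z, index=list(genes), columns=expr.sample_ids)


def multigene_score(zmat: pd.DataFrame, subset: Sequence[str]) -> ScoreVector:
    """Per-sample sum of signed z-scores over ``subset`` rows."""
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    missing = [g for g in subset if g not in zmat.index]
    if missing:
        raise KeyError(f"genes not in z matrix: {missing}")
    scores = zmat.loc[subset].to_numpy().sum(axis=0)
    return ScoreVector(list(zmat.columns), scores)


def median_split(scores: ScoreVector) -> ScoreVector:
    """Dichotomize at the sample median: score > median -> 'higher'.

    Ties at the cutoff go to 'lower', so the higher group strictly
    exceeds the cutoff and the split is deterministic for tied scores.
    """
    s = scores.scores
    if s.size < 4:
        raise ValueError("median split needs at least 4 samples")
    cutoff = float(np.median(s))
    groups = np.where(s > cutoff, "higher", "lower")
    if (groups == "higher").all() or (groups == "lower").all():
        raise ValueError("degenerate split: all samples on one side of the median")
    return ScoreVector(scores.sample_ids, s, cutoff, groups)


def _rank_table(df: pd.DataFrame, criterion: str) -> pd.DataFrame:
    ok = df[df["status"] == "ok"].copy()
    bad = df[df["status"] != "ok"].copy()
    if criterion == "pval":
        # lowest p, ties -> highest HR -> smallest subset -> lexical
        ok = ok.sort_values(["logrank_p", "hr", "size", "subset"],
                            ascending=[True, False, True, True],
                            kind="stable")
    elif criterion == "hr":
        ok = ok.sort_values(["hr", "logrank_p", "size", "subset"],
                            ascending=[False, True, True, True], kind="stable")
    else:
        raise ValueError(f"unknown criterion {criterion!r} (use 'pval' or 'hr')")
    out = pd.concat([ok, bad], ignore_index=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def additive_search(expr: ExpressionMatrix, clinical: ClinicalTable,
                    candidates: Sequence[str], signs: Sequence[int],
                    endpoint: str = "os", criterion: str = "pval",
                    hr_method: str = "mantel-haenszel") -> CombinationRanking:
    """Exhaustively screen every non-empty candidate subset.

    For each of the 2^k - 1 subsets: multi-gene score, median split,
    log-rank test of higher vs lower.  Subsets whose split or test is
    degenerate are recorded with a failure reason, not silently skipped.

    Scoring uses the tumor samples that carry the requested endpoint;
    z-scores are computed on exactly those samples.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate gene")
    if len(candidates) > MAX_CANDIDATES:
        raise ValueError(
            f"{len(candidates)} candidates would mean 2^{len(candidates)}-1 "
            f"subsets; exhaustive search is capped at {MAX_CANDIDATES}")

    tumor_ids = [s for s in expr.sample_ids if s in set(clinical.tumor_ids())]
    times, events, used_ids = clinical.survival(endpoint, tumor_ids)
    if len(used_ids) < 4:
        raise ValueError("fewer than 4 scored samples with survival data")
    zmat = zscore_transform(expr.subset_samples(used_ids), candidates, signs)
    zvals = zmat.to_numpy()

    rows = []
    k = len(candidates)
    for size in range(1, k + 1):
        for combo in itertools.combinations(range(k), size):
            genes = [candidates[i] for i in combo]
            name = ",".join(genes)
            scores = zvals[list(combo)].sum(axis=0)
            row = {"subset": name, "size": size, "logrank_p": np.nan,
                   "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                   "chi2": np.nan, "status": "ok"}
            try:
                sv = median_split(ScoreVector(used_ids, scores))
                res = logrank_test(times, events, sv.groups,
                                   group_order=("higher", "lower"),
                                   hr_method=hr_method)
                row.update(logrank_p=res.p, hr=res.hr, ci_low=res.ci95[0],
                           ci_high=res.ci95[1], chi2=res.chi2)
            except (ValueError, SurvivalError) as exc:
                row["status"] = f"failed: {exc}"
            rows.append(row)

    df = _rank_table(pd.DataFrame(rows), criterion)
    n_screened = len(df)
    return CombinationRanking(df, criterion, n_screened, endpoint,
                              bonferroni_alpha=0.05 / n_screened)


def evaluate_panel(expr: ExpressionMatrix, clinical: ClinicalTable,
                   panel: PanelDefinition, endpoint: str = "os",
                   hr_method: str = "mantel-haenszel",
                   ) -> tuple[dict[str, KMCurve], LogRankResult, ScoreVector]:
    """Score, median-split and test one fixed panel (figure-style output).

    Returns per-group Kaplan–Meier curves, the log-rank result (higher vs
    lower) and the split score vector.
    """
    tumor_ids = [s for s in expr.sample_ids if s in set(clinical.tumor_ids())]
    times, events, used_ids = clinical.survival(endpoint, tumor_ids)
    zmat = zscore_transform(expr.subset_samples(used_ids), panel.genes, panel.signs)
    sv = median_split(multigene_score(zmat, panel.genes))
    res = logrank_test(times, events, sv.groups,
                       group_order=("higher", "lower"), hr_method=hr_method)
    t = np.asarray(times, float)
    e = np.asarray(events, float)
    curves = {label: km_estimate(t[sv.groups == label], e[sv.groups == label])
              for label in ("higher", "lower")}
    return curves, res, sv
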