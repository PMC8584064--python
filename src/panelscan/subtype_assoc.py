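"""Panel-score distribution across molecular subtypes, with one-way ANOVA.

Groups the per-sample panel score (the signed z-score sum, as computed
by the panel search; a mean-of-z variant is available) by PAM50 or PCS
subtype label and tests for a location difference with the classical
one-way ANOVA F statistic.  Welch's heteroscedasticity-robust variant is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import ClinicalTable
from .panel_search import ScoreVector

__all__ = ["AnovaResult", "score_by_subtype", "anova_oneway", "subtype_association"]

SCHEMES = {"pam50": "pam50", "pcs": "pcs"}


@dataclass
class AnovaResult:
    """One-way ANOVA outcome with per-group summaries."""

    f_value: float
    p: float
    df_between: int
    df_within: float
    group_n: dict[str, int]
    group_mean: dict[str, float]
    method: str = "classic"

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"n": self.group_n, "mean_score": self.group_mean})


def score_by_subtype(scores: ScoreVector, clinical: ClinicalTable,
                     scheme: str = "pam50") -> dict[str, np.ndarray]:
    """Partition scores by subtype label; missing-label samples excluded.

    Raises if fewer than two labels have at least two samples each.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {sorted(SCHEMES)}, got {scheme!r}")
    labels = clinical.df.loc[scores.sample_ids, SCHEMES[scheme]]
    s = pd.Series(scores.scores, index=scores.sample_ids)
    groups = {str(lab): s[labels == lab].to_numpy(float)
              for lab in labels.dropna().unique()}
    usable = {k: v for k, v in groups.items() if v.size >= 2}
    if len(usable) < 2:
        raise ValueError(
            f"need >=2 subtype groups with >=2 samples; got {len(usable)} "
            f"usable of {len(groups)} labelled")
    return dict(sorted(usable.items()))


def anova_oneway(grouped: dict[str, np.ndarray], method: str = "classic",
                 ) -> AnovaResult:
    """One-way ANOVA over grouped scores.

    ``classic`` is the standard between/within mean-square F with an
    F(k-1, n-k) p-value; ``welch`` does not assume equal group variances
    (Welch-Satterthwaite degrees of freedom).
    """
    names = list(grouped)
    arrays = [np.asarray(grouped[g], float) for g in names]
    k = len(arrays)
    ns = np.array([a.size for a in arrays])
    if k < 2 or ns.sum() <= k:
        raise ValueError("ANOVA needs >=2 groups and more samples than groups")
    means = np.array([a.mean() for a in arrays])
    grand = np.concatenate(arrays).mean()

    if method == "classic":
        ss_between = float(np.sum(ns * (means - grand) ** 2))
        ss_within = float(sum(((a - m) ** 2).sum() for a, m in zip(arrays, means)))
        df_b, df_w = k - 1, int(ns.sum()) - k
        if ss_within == 0 and ss_between == 0:
            raise ValueError("all scores identical: F undefined")
        if ss_within == 0:
            f, p = np.inf, 0.0
        else:
            f = (ss_between / df_b) / (ss_within / df_w)
            p = float(stats.f.sf(f, df_b, df_w))
    elif method == "welch":
        w = ns / np.array([a.var(ddof=1) for a in arrays])
        mw = float(np.sum(w * means) / w.sum())
        df_b = k - 1
        num = np.sum(w * (means - mw) ** 2) / df_b
        lam = 3.0 * np.sum((1 - w / w.sum()) ** 2 / (ns - 1)) / (k ** 2 - 1)
        f = float(num / (1 + 2 * lam * (k - 2) / 3))
        df_w = 1.0 / lam
        p = float(stats.f.sf(f, df_b, df_w))
    else:
        raise ValueError(f"unknown method {method!r} (use 'classic' or 'welch')")

    return AnovaResult(float(f), float(p), df_b, float(df_w),
                       {g: int(n) for g, n in zip(names, ns)},
                       {g: float(m) for g, m in zip(names, means)}, method)


def subtype_association(scores: ScoreVector, clinical: ClinicalTable,
                        scheme: str = "pam50", method: str = "classic",
                        ) -> AnovaResult:
    """Convenience wrapper: partition by subtype, then one-way ANOVA."""
    return anova_oneway(score_by_subtype(scores, clinical, scheme), method)
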