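"""Confounder-adjusted panel effect: multivariate Cox regression.

Fits the endpoint on panel group plus the four routine prostate-cancer
clinical covariates, with fixed reference levels:

* panel group — higher vs lower (reference: lower), reusing the median
  split computed on the full scored cohort (group first, adjust second);
* age — continuous, years;
* PSA — continuous, ng/mL;
* TNM group — other vs early (reference: early = T1/T2 N0 M0);
* Gleason group — >7 vs <=7 (reference: <=7).

Missing covariates are handled by complete-case exclusion, with the
exclusion count always reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import ClinicalTable
from .panel_search import ScoreVector
from .survival_core import CoxFit, cox_fit

__all__ = ["AdjustedModelSpec", "AdjustedFit", "fit_adjusted", "build_design"]

#: report rows in the conventional order: panel, age, PSA, TNM, Gleason
COVARIATE_ORDER = ["panel_higher", "age", "psa", "tnm_other", "gleason_gt7"]


@dataclass(frozen=True)
class AdjustedModelSpec:
    """Which endpoint to adjust and which covariates to include."""

    endpoint: str = "os"                      # 'os' or 'pfs'
    covariates: tuple[str, ...] = tuple(COVARIATE_ORDER)
    ties_method: str = "efron"
    panel_reference: str = "lower"            # swapping inverts the panel HR

    def __post_init__(self) -> None:
        if self.endpoint not in ("os", "pfs"):
            raise ValueError(f"endpoint must be 'os' or 'pfs', got {self.endpoint!r}")
        unknown = set(self.covariates) - set(COVARIATE_ORDER)
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")
        if self.panel_reference not in ("lower", "higher"):
            raise ValueError("panel_reference must be 'lower' or 'higher'")


@dataclass
class AdjustedFit:
    """CoxFit plus the bookkeeping a report needs."""

    fit: CoxFit
    endpoint: str
    n_used: int
    n_excluded_missing: int
    excluded_samples: list[str] = field(default_factory=list)

    def report(self) -> pd.DataFrame:
        """Per-covariate table: HR, Lower 95% CI, Higher 95% CI, p value."""
        f = self.fit
        return pd.DataFrame({
            "HR": f.hr,
            "Lower 95% CI": [c[0] for c in f.ci95],
            "Higher 95% CI": [c[1] for c in f.ci95],
            "p Value": f.wald_p,
        }, index=f.names)


def build_design(clinical: ClinicalTable, scores: ScoreVector,
                 spec: AdjustedModelSpec) -> pd.DataFrame:
    """Dummy-coded design matrix for the scored samples (NaN where missing).

    The panel indicator comes from the precomputed median split in
    ``scores`` (1 = non-reference group), so the grouping is identical to
    the one the unadjusted analysis used.
    """
    if scores.groups is None:
        raise ValueError("scores must carry a median split (run median_split first)")
    sub = clinical.df.loc[scores.sample_ids]
    non_ref = "higher" if spec.panel_reference == "lower" else "lower"
    design = pd.DataFrame(index=pd.Index(scores.sample_ids, name="sample_id"))
    design["panel_higher"] = (np.asarray(scores.groups) == non_ref).astype(float)
    design["age"] = sub["age"].to_numpy(float)
    design["psa"] = sub["psa"].to_numpy(float)
    design["tnm_other"] = sub["tnm_group"].map({"early": 0.0, "other": 1.0}).to_numpy()
    design["gleason_gt7"] = sub["gleason_group"].map({"le7": 0.0, "gt7": 1.0}).to_numpy()
    return design[list(spec.covariates)]


def fit_adjusted(clinical: ClinicalTable, scores: ScoreVector,
                 spec: AdjustedModelSpec | None = None) -> AdjustedFit:
    """Multivariate Cox fit of the endpoint on panel group + covariates.

    Samples missing any requested covariate or the endpoint are excluded
    (complete-case); the count and ids of exclusions are reported.
    """
    spec = spec or AdjustedModelSpec()
    design = build_design(clinical, scores, spec)
    sub = clinical.df.loc[scores.sample_ids]
    t = sub[f"{spec.endpoint}_time"].to_numpy(float)
    e = sub[f"{spec.endpoint}_event"].to_numpy(float)
    complete = design.notna().all(axis=1).to_numpy() & np.isfinite(t) & np.isfinite(e)
    excluded = [s for s, ok in zip(scores.sample_ids, complete) if not ok]
    if not complete.any():
        raise ValueError("all samples excluded by missing covariates/endpoint")
    fit = cox_fit(t[complete], e[complete], design.to_numpy(float)[complete],
                  names=list(design.columns), ties_method=spec.ties_method)
    return AdjustedFit(fit, spec.endpoint, int(complete.sum()), len(excluded), excluded)
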