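"""From-scratch survival statistics: Kaplan–Meier, log-rank, Cox PH.

These are the primitives behind the median-split survival screen and the
multivariate confounder adjustment:

* :func:`km_estimate` — product-limit estimator with Greenwood variance.
* :func:`logrank_test` — two-group log-rank (Mantel–Haenszel) test.  The
  reported hazard ratio is the O/E ratio ``(O1/E1)/(O2/E2)`` with a
  Tsiatis-style standard error ``sqrt(1/E1 + 1/E2)`` on the log scale,
  i.e. the "log-rank HR" produced by common Kaplan–Meier tools.  A
  univariate-Cox HR can be requested instead via ``hr_method="cox"``.
* :func:`cox_fit` — Cox proportional hazards by Newton–Raphson
  maximization of the partial likelihood, with the Efron correction for
  tied event times by default (Breslow available), Wald standard errors
  from the inverse observed information, and explicit convergence
  diagnostics.

Conventions: event flags are 0 (censored) / 1 (event); subjects with an
event at time 0 are invalid; subjects censored at time 0 contribute
nothing and are dropped with a warning.  Confidence intervals are 95%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CoxFit",
    "SurvivalError",
    "km_estimate",
    "km_by_group",
    "logrank_test",
    "cox_fit",
]

Z_95 = float(stats.norm.ppf(0.975))  # 1.959963984540054


class SurvivalError(ValueError):
    """Invalid survival input (negative times, bad event flags, degenerate data)."""


def _validate_survival(times, events) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Validate and filter a (times, events) pair.

    Returns (times, events, keep_mask) where keep_mask marks subjects
    retained relative to the input (censored-at-zero subjects dropped).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.ndim != 1 or e.shape != t.shape:
        raise SurvivalError("times and events must be 1-D arrays of equal length")
    if t.size == 0:
        raise SurvivalError("empty survival input")
    if not np.all(np.isfinite(t)):
        raise SurvivalError("non-finite survival time")
    if np.any(t < 0):
        raise SurvivalError("negative survival time")
    if not np.all(np.isin(e, (0.0, 1.0))):
        raise SurvivalError("event flags must be 0 or 1")
    if np.any((t == 0) & (e == 1)):
        raise SurvivalError("event at time 0 is invalid")
    keep = ~((t == 0) & (e == 0))
    if not np.all(keep):
        warnings.warn(f"{int((~keep).sum())} subject(s) censored at time 0 dropped",
                      stacklevel=3)
    if not np.any(keep):
        raise SurvivalError("no subjects remain after dropping censored-at-zero")
    return t[keep], e[keep], keep


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival curve.

    ``event_times`` are the sorted distinct times with at least one event;
    ``survival[i]`` is S(t) just after ``event_times[i]``.  ``greenwood_var``
    is the Greenwood estimate of Var[S(t)].
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    greenwood_var: np.ndarray
    n_subjects: int

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        i = int(np.searchsorted(self.event_times, t, side="right"))
        return 1.0 if i == 0 else float(self.survival[i - 1])


def km_estimate(times: Sequence[float], events: Sequence[float]) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    At each distinct event time ``t_i`` with ``d_i`` events among ``n_i``
    subjects at risk, the survival estimate multiplies by ``1 - d_i/n_i``;
    censored subjects leave the risk set after their censoring time.
    """
    t, e, _ = _validate_survival(times, events)
    n = t.size
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    ev_times = np.unique(ts[es == 1])
    if ev_times.size == 0:
        return KMCurve(ev_times, np.ones(0), np.zeros(0, int), np.zeros(0, int),
                       np.zeros(0), n)
    # at risk at time u = subjects with time >= u
    at_risk = n - np.searchsorted(ts, ev_times, side="left")
    d = np.array([np.sum((ts == u) & (es == 1)) for u in ev_times])
    surv = np.cumprod(1.0 - d / at_risk)
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = d / (at_risk * (at_risk - d))
        inc[~np.isfinite(inc)] = np.nan  # S hit 0: Greenwood undefined beyond
    gw = surv ** 2 * np.nancumsum(inc)
    return KMCurve(ev_times, surv, at_risk.astype(int), d.astype(int), gw, n)


def km_by_group(times, events, groups) -> dict[str, KMCurve]:
    """Kaplan–Meier per group label; pair with :func:`logrank_test` for plots."""
    t = np.asarray(times, float)
    e = np.asarray(events, float)
    g = np.asarray(groups)
    return {str(label): km_estimate(t[g == label], e[g == label])
            for label in np.unique(g)}


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

@dataclass
class LogRankResult:
    """Two-group log-rank test with Mantel–Haenszel hazard ratio."""

    chi2: float
    p: float
    hr: float
    ci95: tuple[float, float]
    observed: tuple[float, float]   # events in (group1, group2)
    expected: tuple[float, float]
    variance: float
    group_names: tuple[str, str]
    n_per_group: tuple[int, int]


def _logrank_core(t: np.ndarray, e: np.ndarray, in_g1: np.ndarray,
                  ) -> tuple[float, float, float, float]:
    """(O1, E1, V, O_total) from the per-event-time hypergeometric tabulation.

    Arrays need not be sorted.  At each distinct event time: observed
    events in group 1 vs expectation ``d * n1/n`` under the null, with
    hypergeometric variance ``d (n1/n)(1 - n1/n)(n - d)/(n - 1)``.
    """
    order = np.argsort(t, kind="stable")
    ts, es, g1 = t[order], e[order], in_g1[order]
    n = ts.size
    ev_mask = es == 1
    ev_times = np.unique(ts[ev_mask])
    # at-risk counts via searchsorted on the globally and per-group sorted times
    t1 = np.sort(t[in_g1], kind="stable")
    n_at = n - np.searchsorted(ts, ev_times, side="left")
    n1_at = t1.size - np.searchsorted(t1, ev_times, side="left")
    # events per distinct time, overall and in group 1
    te = ts[ev_mask]
    d = np.searchsorted(te, ev_times, side="right") - np.searchsorted(te, ev_times, side="left")
    te1 = np.sort(t[in_g1 & (e == 1)], kind="stable")
    d1 = np.searchsorted(te1, ev_times, side="right") - np.searchsorted(te1, ev_times, side="left")

    frac1 = n1_at / n_at
    e1 = d * frac1
    with np.errstate(divide="ignore", invalid="ignore"):
        v = d * frac1 * (1.0 - frac1) * (n_at - d) / (n_at - 1.0)
    v[n_at <= 1] = 0.0
    return float(d1.sum()), float(e1.sum()), float(v.sum()), float(d.sum())


def logrank_test(times, events, groups, group_order: Sequence[str] | None = None,
                 hr_method: str = "mantel-haenszel") -> LogRankResult:
    """Two-group log-rank test.

    Parameters
    ----------
    groups : array-like
        Per-subject labels; exactly two distinct values.
    group_order : sequence of two labels, optional
        The first label is the numerator group of the hazard ratio
        (e.g. ``("higher", "lower")``).  Defaults to sorted label order.
    hr_method : {"mantel-haenszel", "cox"}
        MH O/E-ratio HR (default) or a univariate-Cox HR on the group
        indicator; the chi-square statistic is the log-rank one either way.
    """
    t = np.asarray(times, float)
    e = np.asarray(events, float)
    g = np.asarray(groups)
    tt, ee, keep = _validate_survival(t, e)
    g = g[keep]
    labels = [str(x) for x in np.unique(g)]
    if len(labels) != 2:
        raise SurvivalError(f"log-rank needs exactly 2 groups, got {labels}")
    if group_order is not None:
        go = [str(x) for x in group_order]
        if sorted(go) != sorted(labels):
            raise SurvivalError(f"group_order {go} does not match labels {labels}")
        labels = go
    in_g1 = g.astype(str) == labels[0]
    if in_g1.all() or not in_g1.any():
        raise SurvivalError("one group is empty")

    o1, e1, v, o_tot = _logrank_core(tt, ee, in_g1)
    if o_tot == 0 or v == 0:
        raise SurvivalError("no events (or no variance): log-rank undefined")
    chi2 = (o1 - e1) ** 2 / v
    p = float(stats.chi2.sf(chi2, df=1))
    o2, e2 = o_tot - o1, o_tot - e1

    if hr_method == "cox":
        fit = cox_fit(tt, ee, in_g1.astype(float)[:, None], names=["group"])
        hr, ci = fit.hr[0], (fit.ci95[0][0], fit.ci95[0][1])
    elif hr_method == "mantel-haenszel":
        with np.errstate(divide="ignore", invalid="ignore"):
            hr = (o1 / e1) / (o2 / e2) if (o2 > 0 and e2 > 0 and e1 > 0) else np.inf
        if o1 == 0:
            hr = 0.0
        se = np.sqrt(1.0 / e1 + 1.0 / e2)
        with np.errstate(divide="ignore"):
            log_hr = np.log(hr) if 0 < hr < np.inf else np.nan
        ci = (float(np.exp(log_hr - Z_95 * se)), float(np.exp(log_hr + Z_95 * se)))
    else:
        raise ValueError(f"unknown hr_method {hr_method!r}")

    return LogRankResult(float(chi2), p, float(hr), ci, (o1, o2), (e1, e2), v,
                         (labels[0], labels[1]),
                         (int(in_g1.sum()), int((~in_g1).sum())))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Cox PH fit: per-covariate coefficients, HRs, Wald inference.

    ``converged`` False flags unreliable results (e.g. monotone likelihood
    under complete separation); estimates are still reported with the
    diagnostic in ``message``.
    """

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci95: list[tuple[float, float]]
    wald_p: np.ndarray
    log_likelihood: float
    n_iterations: int
    converged: bool
    ties_method: str
    n_subjects: int
    n_events: int
    message: str = ""

    def summary(self) -> "object":
        import pandas as pd
        return pd.DataFrame({
            "coef": self.coef, "HR": self.hr, "se": self.se,
            "ci95_low": [c[0] for c in self.ci95],
            "ci95_high": [c[1] for c in self.ci95],
            "p": self.wald_p,
        }, index=self.names)


def _cox_loglik_deriv(beta: np.ndarray, t: np.ndarray, e: np.ndarray,
                      X: np.ndarray, efron: bool,
                      ) -> tuple[float, np.ndarray, np.ndarray]:
    """Partial log-likelihood, score vector and observed information.

    Subjects must be sorted by time ascending.  For each distinct event
    time the risk set is everyone with time >= t; Efron's correction
    down-weights the tied deaths' own contribution within the tie group.
    """
    n, p = X.shape
    eta = X @ beta
    with np.errstate(over="ignore"):
        w = np.exp(eta)
    if not np.all(np.isfinite(w)):  # wildly off beta during step-halving
        return -np.inf, np.zeros(p), np.eye(p)
    wX = w[:, None] * X
    wXX = np.einsum("i,ij,ik->ijk", w, X, X)

    ll = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))

    # suffix sums over the risk set: subjects i..n-1 have time >= t[i]
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wX[::-1], axis=0)[::-1]
    S2 = np.cumsum(wXX[::-1], axis=0)[::-1]

    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        tied = np.arange(i, j)[e[i:j] == 1]
        d = tied.size
        if d > 0:
            s0_r, s1_r, s2_r = S0[i], S1[i], S2[i]
            s0_d = w[tied].sum()
            s1_d = wX[tied].sum(axis=0)
            s2_d = wXX[tied].sum(axis=0)
            ll += eta[tied].sum()
            for l in range(d):
                f = (l / d) if efron else 0.0
                a0 = s0_r - f * s0_d
                a1 = s1_r - f * s1_d
                a2 = s2_r - f * s2_d
                ll -= np.log(a0)
                m = a1 / a0
                score -= m
                info += a2 / a0 - np.outer(m, m)
            score += X[tied].sum(axis=0)
        i = j
    return ll, score, info


def cox_fit(times, events, covariates, names: Sequence[str] | None = None,
            ties_method: str = "efron", max_iter: int = 50,
            tol: float = 1e-9) -> CoxFit:
    """Fit a Cox proportional hazards model by Newton–Raphson.

    Parameters
    ----------
    covariates : ndarray (n, p)
        Finite covariate matrix; a constant column is an error (it is not
        identifiable in the partial likelihood) and is reported by name.
    ties_method : {"efron", "breslow"}
        Tie handling in the partial likelihood; the two agree exactly when
        no event times are tied.

    Convergence: max \\|score\\| < tol or relative log-likelihood change
    < tol within ``max_iter`` Newton steps (with step-halving).  A fit
    stopped at ``max_iter``, or with diverging coefficients (monotone
    likelihood / complete separation), carries ``converged=False``.
    """
    if ties_method not in ("efron", "breslow"):
        raise ValueError(f"unknown ties_method {ties_method!r}")
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    t = np.asarray(times, float)
    e = np.asarray(events, float)
    tt, ee, keep = _validate_survival(t, e)
    X = X[keep]
    n, p = X.shape
    if names is None:
        names = [f"x{k}" for k in range(p)]
    names = list(names)
    if len(names) != p:
        raise ValueError("names length does not match covariate count")
    if not np.all(np.isfinite(X)):
        raise SurvivalError("non-finite covariate value")
    if ee.sum() == 0:
        raise SurvivalError("no events: partial likelihood is constant")
    const = np.where(X.std(axis=0) == 0)[0]
    if const.size:
        raise SurvivalError(f"constant covariate: {names[const[0]]!r}")

    order = np.argsort(tt, kind="stable")
    ts, es, Xs = tt[order], ee[order], X[order]
    # center for numerical stability; slopes are unaffected
    x_mean = Xs.mean(axis=0)
    Xc = Xs - x_mean
    efron = ties_method == "efron"

    beta = np.zeros(p)
    ll, score, info = _cox_loglik_deriv(beta, ts, es, Xc, efron)
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            message = "singular information matrix"
            break
        # step-halving to guarantee likelihood ascent
        factor = 1.0
        for _ in range(30):
            beta_new = beta + factor * step
            ll_new, score_new, info_new = _cox_loglik_deriv(beta_new, ts, es, Xc, efron)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        rel_change = abs(ll_new - ll) / max(abs(ll), 1.0)
        beta, ll, score, info = beta_new, ll_new, score_new, info_new
        if np.max(np.abs(score)) < tol or rel_change < tol:
            converged = True
            break
    if not converged and not message:
        message = ("did not converge (possible monotone likelihood / "
                   "complete separation)")
    if converged and np.max(np.abs(beta)) > 20:
        converged = False
        message = "coefficient diverged: monotone likelihood suspected"

    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    with np.errstate(over="ignore"):
        hr = np.exp(beta)
        ci = [(float(np.exp(b - Z_95 * s)), float(np.exp(b + Z_95 * s)))
              for b, s in zip(beta, se)]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    wald_p = 2.0 * stats.norm.sf(np.abs(z))

    return CoxFit(names, beta, se, hr, ci, wald_p, float(ll), it, converged,
                  ties_method, n, int(ee.sum()), message)
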