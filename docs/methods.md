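# Methods

## The discovery procedure

panelscan implements a prognostic-signature discovery workflow for
tumor expression cohorts: differential-expression filtering of a
candidate gene universe, an exhaustive survival screen over all subsets
of the filtered candidates, confounder adjustment of the winning panel,
and a subtype-association test. The sections below state the models,
the numerical choices, and what the synthetic validation does and does
not establish.

### Differential expression and the SDE filter

Raw counts are normalized with median-of-ratios size factors: the
reference is the per-gene geometric mean across samples (genes with any
zero count drop out of the reference), and each sample's factor is the
median of its count/reference ratios. Per gene, a negative-binomial
Wald test compares tumor and normal means: dispersion α is estimated by
method of moments, (s² − μ)/μ², pooled within condition groups by
residual degrees of freedom and floored at 1e−8; the effect is
log₂((μ̂_T + ½)/(μ̂_N + ½)) with a 0.5 pseudocount guarding zero means;
its standard error comes from the delta method with
Var(K/f) = μ/f + αμ² per sample. Two-sided normal p-values are
BH-adjusted across genes (statsmodels' step-up).

This engine is deliberately simpler than DESeq2 — no dispersion
shrinkage, Cox–Reid adjustment, or outlier refitting — because the
package's contribution lies downstream of the DE engine: the filter and
everything after it must be faithful, and an externally computed DE
table (same columns) can be substituted via `read_de_table`.

A gene is a *significantly differentially expressed* (SDE) candidate
when |log₂FC| > 1 and adjusted p < 0.05, both strict. A flag switches
the filter to raw p, since published descriptions of this style of
filter are sometimes ambiguous about which p-value the 0.05 applies to;
adjusted is the default because candidate tables conventionally report
the adjusted column. Each candidate carries sign(log₂FC). All-zero
genes produce the defined degenerate output (log₂FC 0, p 1) rather than
vanishing, for auditability.

The method-of-moments engine is approximately calibrated for moderate
group sizes (the suite verifies the null rejection rate at n = 60 per
group over 2000 genes against a binomial envelope) and assumes DE genes
are a small fraction of the genome — the median-of-ratios assumption.
Cohorts where a large share of genes shift will bias fold changes
toward zero.

### Additive-effect search

For the k SDE candidates, expression (on log scale for counts the
z-transform sees, or as given for log-normalized input) is z-scored
per gene **across exactly the scored tumor samples** — adding or
removing normal samples cannot change any downstream number — then
multiplied by the candidate's direction sign. Any down-regulated
candidate is flipped, generalizing the usual practice of negating the
one down-regulated gene so that a high panel score always reads
"more tumor-like".

Every non-empty subset (2ᵏ − 1; a guard refuses k > 20) is scored by
the per-sample sum of signed z-scores, dichotomized at the sample
median (ties to "lower", so the higher group strictly exceeds the
cutoff and tied scores split deterministically), and tested with the
two-group log-rank test. Subsets are ranked by smallest p with a
highest-HR, then smallest-size, then lexical tie-break — a total order,
so ranking is reproducible; ranking by HR is available as an
alternative criterion since "most significant" and "largest effect" are
both defensible winners and can disagree. Degenerate subsets (e.g. a
constant score) are recorded with a failure reason and rank last, never
silently dropped.

No multiplicity correction is applied across the subsets — the ranking
exists to *select*, not to test — but the report always carries the
screen size and a Bonferroni reference level, because the winner's
unadjusted p-value is strongly anti-conservative: under the global null
the selected subset's log-rank test rejects at far above the nominal
level (the acceptance suite measures ≈0.9 at n = 200 with k = 8 versus
≈0.05 for a prespecified split). Any downstream use of the winning
panel's p-value should treat it as descriptive.

The z-transform is applied before the sign flip; the two orders differ
only in the direction of mean-centering and yield identical splits.

### Survival statistics

Implemented from first principles and cross-checked against independent
oracles (hand tabulations, 1-D likelihood grid search) and lifelines:

* **Kaplan–Meier**: product-limit estimator with Greenwood variance.
* **Log-rank**: per distinct event time, observed minus hypergeometric
  expected events with variance d(n₁/n)(1−n₁/n)(n−d)/(n−1);
  χ² = (O₁−E₁)²/V on 1 df. The reported hazard ratio is the
  Mantel–Haenszel O/E ratio (O₁/E₁)/(O₂/E₂) with SE √(1/E₁+1/E₂) on
  the log scale — the "log-rank HR" of common KM tools; a
  univariate-Cox HR is available via `hr_method="cox"` since screening
  tools differ in which estimate they print.
* **Cox PH**: Newton–Raphson on the partial likelihood with Efron's
  correction for ties (Breslow optional; they coincide without ties),
  step-halving to guarantee ascent, convergence at max |score| < 1e−9
  or relative log-likelihood change < 1e−9 within 50 iterations, Wald
  SEs from the inverse observed information, covariates centered for
  conditioning. Constant covariates are rejected by name; monotone
  likelihood (complete separation) or |β| > 20 flags the fit
  non-converged with a diagnostic rather than failing silently.

Subjects with an event at time 0 are invalid; subjects censored at 0
are dropped with a warning. Confidence level is fixed at 95%.

### Confounder adjustment

The multivariate model regresses the endpoint on the panel indicator
(higher vs lower; reference lower) plus age (years), PSA (ng/mL), TNM
group (other vs T1/T2N0M0) and Gleason group (>7 vs ≤7), the standard
baseline covariates of a primary prostate-cancer cohort. The panel
indicator reuses the median split computed on the **full** scored
cohort — grouping first, adjusting second — rather than re-splitting
the complete-case subset. Missing covariates trigger complete-case
exclusion with the count and sample ids always reported; imputation is
out of scope.

### Subtype association

The per-sample panel score (the same signed z-sum the search uses; the
F statistic is invariant to rescaling, so a mean-of-z aggregation gives
the identical test) is grouped by PAM50 or PCS label and tested with
the classical one-way ANOVA F = MS_between/MS_within against
F(k−1, n−k); Welch's variant is available for unequal variances.
Missing labels are excluded with a count.

## The synthetic cohort generator

The generator exists so that every claim above is measurable. It
emulates:

* **Expression**: NB counts, per-gene baseline means lognormal around
  `nb_mean` (default 500, log-sd 1), common dispersion `nb_dispersion`
  (default 0.2, typical for bulk RNA-seq); planted genes' tumor mean is
  the normal mean × 2^log₂FC.
* **Survival**: exponential event times with hazard
  h₀·exp(β·score), where the score is the signed z-sum of the planted
  *prognostic* genes computed from log₂(count+1) tumor expression —
  exactly the statistic the search evaluates, giving a closed-form
  target for recovery. Censoring is independent uniform over the
  follow-up window for a `censor_rate` fraction, administrative at
  `followup_max` otherwise.
* **Covariates**: independent draws (age ~ N(61, 7²) years, PSA
  lognormal with median ≈ 7.4 ng/mL, Gleason >7 with probability 0.45,
  TNM other with 0.30), matching the marginals of a primary
  prostatectomy cohort; optional log-odds slopes can correlate Gleason
  and TNM with the score, but the default keeps them independent so
  adjusted-model tests have a known truth (covariate HR = 1).
* **Subtypes**: ordinal-logit draws on the standardized score with
  aggressiveness ordering LumA < Basal < LumB and PCS2 < PCS3 < PCS1,
  so the ANOVA stage has a monotone signal.

Only tumors carry survival, covariates and labels; normals carry
condition and counts only, mirroring the tumor-vs-adjacent-normal
design.

Defaults mirror the shape of the TCGA-PRAD discovery setting: 497
tumors, 153 candidate genes, eight planted DE genes (seven up, one
down-regulated at −1.20) with the four-gene prognostic subset including
the down-regulated gene. The adjacent-normal count is not part of the
published cohort description; 52 is used as a typical adjacent-normal
complement. Real TCGA overall survival is far more heavily censored
than these defaults; the generator's baseline hazards (4e−4/day OS,
6e−4/day PFS over a 10-year window, `censor_rate` 0.5) are chosen to
yield a PFS-like event fraction (roughly half to two-thirds observed
events) so that recovery and calibration experiments have adequate
event counts at a few hundred samples. `planted_panel_config` pushes
the planted fold changes to ≥ |1.3| so the strict filter recovers all
eight reliably; `default_config` keeps two genes at the published
borderline values (1.00–1.02), where recovery is intentionally
marginal.

What passing tests on this generator do **not** show: robustness to
batch effects, GC/length bias, gene–gene correlation beyond the planted
signature, informative censoring, non-proportional hazards, or
misclassified subtype labels — none of which the generator emulates.

## Problem sizes used in validation

The suite validates enumeration completeness at 500 tumors (255
subsets, well under a minute), type-I calibration with 1000 null
replicates at n = 200, and planted-panel recovery over 50 cohorts of
400 tumors (top-1 rate ≥ 80% observed ≈ 0.9; the Cox coefficient on the
true score recovers β = 0.8 within a few percent). The acceptance
script repeats these measurements from scratch at the same sizes.

## Known limitations

* Exhaustive search only: no greedy/heuristic mode for k > 20, no
  cross-validation or external validation of the selected panel — the
  screen's selection bias is reported, not corrected.
* The NB Wald engine is a calibrated but unshrunken DE test; for small
  cohorts or heavy-tailed dispersion use an external DESeq2 table.
* No time-varying covariates, stratified Cox, frailty, or
  proportional-hazards diagnostics.
* Gene identifiers are matched as exact strings; symbol aliasing is an
  upstream concern.
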