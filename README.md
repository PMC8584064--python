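# panelscan

Prognostic gene-panel discovery for tumor cohorts by exhaustive
median-split survival screening — the "additive effect" analysis used to
derive multi-gene expression signatures such as DNA-damage-repair panels
in prostate cancer — packaged as a tested, reusable pipeline with a
synthetic-cohort generator so every stage can be validated without
access to TCGA-scale data.

## What it does

Given a gene-by-sample expression matrix (tumor and adjacent-normal
samples), a per-sample clinical table (overall and progression-free
survival, age, PSA, Gleason and TNM groups, optional PAM50/PCS subtype
labels) and a candidate gene universe (e.g. GMT pathway files), the
pipeline:

1. **Differential expression** — a negative-binomial Wald test
   (median-of-ratios size factors, method-of-moments dispersion) calls
   tumor-vs-normal log₂ fold changes; genes with |log₂FC| > 1 and
   BH-adjusted p < 0.05 become *SDE candidates*, each carrying
   sign(log₂FC). A precomputed DE table (e.g. DESeq2 output) can be
   supplied instead.
2. **Additive-effect search** — each candidate is z-scored across the
   scored tumors, zᵢⱼ = (xᵢⱼ − x̄ᵢ)/sᵢ, multiplied by its direction sign
   (down-regulated genes are flipped so "higher" always means more
   tumor-like). For every non-empty subset S of the k candidates
   (2ᵏ − 1 subsets; 255 for k = 8) the multi-gene score
   Zⱼ = Σ_{i∈S} sᵢ zᵢⱼ is split at its sample median, the two groups
   are compared with the log-rank test, and subsets are ranked by
   p-value (Mantel–Haenszel HR = (O₁/E₁)/(O₂/E₂) reported with a
   Tsiatis-style 95% CI).
3. **Confounder adjustment** — the winning panel's higher/lower group
   enters a multivariate Cox proportional-hazards model (Efron ties)
   next to age, PSA, TNM group (T1/T2N0M0 vs others) and Gleason group
   (≤7 vs >7), reproducing the standard adjusted-HR table.
4. **Subtype association** — one-way ANOVA of the panel score across
   PAM50 (LumA/LumB/Basal) or PCS (PCS1–3) labels.

Kaplan–Meier, log-rank and Cox regression are implemented from scratch
(validated against independent oracles and lifelines in the test
suite). The synthetic-cohort generator plants NB-distributed counts
with known fold changes and a proportional-hazards survival signal
driven by the planted signature, so recovery, calibration and the
multiplicity cost of screening 255 correlated subsets can all be
measured.

## Worked example

```python
import panelscan as ps

cfg = ps.planted_panel_config(seed=7)        # 497 tumors, 52 normals, 153 genes
expr, clin, truth = ps.generate_cohort(cfg)  # 8 planted DE genes, 4 drive hazard
result = ps.run_analysis(expr, clin)

print("SDE genes:", [r.gene_id for r in result.sde])
print("subsets screened:", result.ranking.n_screened)
print("selected panel:", result.panel.genes, "signs:", result.panel.signs)
os_res = result.evaluations["os"]
print(f"OS log-rank: HR={os_res.hr:.2f} "
      f"(95% CI {os_res.ci95[0]:.2f}-{os_res.ci95[1]:.2f}), p={os_res.p:.3g}")
print(result.adjusted["os"].report().round(4))
```

prints

```
SDE genes: ['G0005', 'G0026', 'G0047', 'G0068', 'G0089', 'G0110', 'G0131', 'G0152']
subsets screened: 255
selected panel: ['G0089', 'G0110', 'G0131', 'G0152'] signs: [1, 1, -1, 1]
OS log-rank: HR=4.54 (95% CI 3.58-5.76), p=1.31e-41
                  HR  Lower 95% CI  Higher 95% CI  p Value
panel_higher  5.1609        3.9875         6.6796   0.0000
age           1.0121        0.9961         1.0284   0.1378
psa           0.9953        0.9842         1.0066   0.4172
tnm_other     0.9915        0.7814         1.2581   0.9440
gleason_gt7   1.2394        0.9871         1.5561   0.0646
```

All eight planted DE genes pass the SDE filter, the search screens all
255 of their subsets, and the winner is exactly the four genes whose
signed z-sum was planted as the hazard driver (`truth.prognostic_genes`),
including the down-regulated gene with sign −1. The adjusted Cox table
shows the panel effect surviving adjustment while the clinical
covariates — independent of survival in this generator — sit near HR 1.

The same workflow is available from the shell:

```bash
panelscan simulate --seed 7 --outdir cohort
panelscan run --expr cohort/expression.tsv --clinical cohort/clinical.tsv \
              --outdir results --seed 7
```

which writes the DE table, the full 255-row ranking, the panel and
adjusted-Cox tables, the subtype ANOVA and a JSON manifest recording
seed, thresholds and the counts at every filter step.

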