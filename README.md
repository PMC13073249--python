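# stratmeta

Expression-stratified survival and differential-correlation meta-analysis
for tumor transcriptomics cohorts.

`stratmeta` is built for the common prognostic-biomarker design in which a
candidate marker gene (here, *PROS1* in pancreatic ductal adenocarcinoma)
is dichotomized within each cohort, survival is compared between the low-
and high-expression strata, the per-cohort effects are pooled across
cohorts, and co-expression of a curated gene panel with the marker is
compared between the two strata. Everything the pipeline needs is either a
cBioPortal-style TSV export (expression matrix + clinical table) or a
synthetic study produced by the built-in generator, so the whole analysis
is testable without any downloads.

## The model

**Stratification.** Within each cohort the marker threshold is the trimmed
mean of marker expression (default: 5% of each tail removed before
averaging). A sample is HIGH iff its marker expression ≥ threshold.

**Survival.** Records with 0 months or more than 30 months of follow-up
are removed (0 < t ≤ 30 retained). For each cohort the Mantel–Haenszel
log-rank machinery sums, over distinct event times, the observed events in
the HIGH stratum (O), their hypergeometric expectation (E) and variance
(V), giving

    HR = exp((O−E)/V),   95% CI = exp((O−E)/V ± 1.96/√V),
    χ² = (O−E)²/V  (1 df, two-tailed p).

Cohort hazard ratios are pooled under an inverse-variance fixed-effects
model on the log scale, with per-study standard errors recovered from the
CI width, SEᵢ = (ln Uᵢ − ln Lᵢ)/(2·1.96), weights wᵢ = 1/SEᵢ², pooled
SE = 1/√Σwᵢ. Per-cohort two-tailed p-values are combined by the weighted
Stouffer Z-method, zᵢ = signᵢ·Φ⁻¹(1 − pᵢ/2), Z = Σwᵢzᵢ/√Σwᵢ², with √n
weights by default. A single-covariate Cox model (Newton iteration, Efron
ties) is available for the continuous, non-dichotomized marker.

**Correlation.** Within each cohort and stratum, Spearman's ρ between the
marker and each panel gene (pairwise-complete; |ρ| = 1 excluded) is mapped
to Fisher's z′ = ½ln((1+ρ)/(1−ρ)) and pooled across cohorts with weights
nᵢ − 3; pooled SE = 1/√Σ(nᵢ−3); the pooled z′ and its CI are
back-transformed with tanh. P-values are Stouffer-combined with the same
n−3 weights; heterogeneity is summarized by Cochran's Q, its χ²(k−1) p,
and I² = max(0, (Q−df)/Q)·100.

**Classification.** Per gene, Δρ = ρ_high − ρ_low. Direction: |Δρ| < 0.29
"Negligible", otherwise "Decreased"/"Increased" by sign. Interpretation:
bands apply only when at least one stratum reaches |ρ| ≥ 0.3; below that
gate, or for |Δρ| < 0.60, the gene is an "Independent correlation";
otherwise |Δρ| ∈ [0.60, 0.70) is a lower-, [0.70, 0.80) an intermediate-,
and [0.80, 1.00] a high-magnitude change (positive Δρ ≥ 0.60 is
"Strengthened").

## Worked example

Simulate a three-cohort study under the default conditions (cohorts of
143/142/112 samples, true HIGH-vs-LOW hazard ratio 0.581, stratum-specific
correlation targets taken from the reference panel) and run both
pipelines:

```sh
stratmeta simulate --seed 5 --out demo/sim
printf 'MMP2\nSNAI2\nSLC2A1\nCASP3\nNULL1\n' > demo/panel.txt
stratmeta run-all \
  --expression demo/sim/SIM0_expression.tsv \
  --expression demo/sim/SIM1_expression.tsv \
  --expression demo/sim/SIM2_expression.tsv \
  --clinical demo/sim/SIM0_clinical.tsv \
  --clinical demo/sim/SIM1_clinical.tsv \
  --clinical demo/sim/SIM2_clinical.tsv \
  --genes demo/panel.txt --out demo/out
```

`demo/out/hazard_ratios.tsv`:

```
cohort  n    hr     ci_low  ci_high  p         weight_pct
SIM0    136  0.729  0.509   1.046    8.63e-02  39.228
SIM1    134  0.586  0.398   0.861    6.57e-03  34.244
SIM2    105  0.384  0.248   0.596    1.90e-05  26.527
Pooled  375  0.571  0.455   0.715    8.64e-07  100.0
```

The pooled row is the inverse-variance combination of the three cohort
rows: here the estimate 0.571 sits close to the generator's true hazard
ratio of 0.581, and its CI excludes 1 even though one cohort alone does
not. `demo/out/differential_correlation.tsv` (first columns):

```
gene    rho_low  rho_high  delta_rho  direction   interpretation
CASP3   0.329    0.325     -0.004     Negligible  Independent correlation
NULL1   0.057    -0.001    -0.058     Negligible  Independent correlation
SLC2A1  0.209    -0.302    -0.511     Decreased   Independent correlation
SNAI2   0.416    -0.358    -0.774     Decreased   Intermediate magnitude Δρ
MMP2    0.418    -0.416    -0.834     Decreased   High magnitude Δρ
```

MMP2 was generated with stratum targets (0.468, −0.382) and is recovered
as a high-magnitude loss of positive co-expression in the HIGH stratum;
the null gene stays uncorrelated and fails the |ρ| ≥ 0.3 gate.

Pooling can also start from an already-summarized per-cohort table
(`stratmeta pool-hr --studies table.tsv`), which is how the published
reference rows shipped in `stratmeta.reference` are combined.

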