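# Methods

This note documents the statistical procedures implemented in `stratmeta`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data generator does and does not emulate.

## Stratification

Each cohort is dichotomized at its own threshold: the arithmetic mean of
marker-gene expression after percentile tail-trimming. Trimming removes
values strictly below the `fraction` quantile and strictly above the
`1 − fraction` quantile (default `fraction = 0.05`, both tails; an
upper-tail-only mode is provided because single-tail trimming is sometimes
preferred when only high outliers are implausible). Quantiles use linear
interpolation of order statistics — the common spreadsheet convention —
so thresholds are reproducible against spreadsheet-based analyses.
Trimming exists to robustify the mean, not to exclude patients: trimmed
samples are labelled and retained by default (`drop_trimmed` reverses
this). Ties at the threshold are HIGH, i.e. the rule is expression ≥
threshold. The mean (rather than median) cut-point assumes marker
expression is approximately normal after trimming, so that "high" means
genuinely above-average rather than merely upper half.

## Survival window

Records with exactly 0 months, or more than 30 months, of recorded
follow-up are removed before any survival computation; the 30-month
boundary itself is retained. The filter applies to the recorded time
regardless of event status (a 0-month censoring is removed as well — the
rule is on the recorded survival time). The 30-month horizon reflects the
short survival of pancreatic ductal adenocarcinoma; note that removing
(rather than administratively censoring) long survivors conditions the
risk sets on the window, which is mirrored here as part of the specified
procedure rather than corrected. Removal counts are reported by reason so
the per-cohort bookkeeping is auditable.

## Per-cohort survival statistics

* **Kaplan–Meier.** Product-limit estimator (via lifelines), with tied
  events processed before censorings at the same time. Exposed with a risk
  table (at-risk, events, censored per distinct time).
* **Mantel–Haenszel log-rank.** At each distinct event time the 2×2 table
  of stratum × event over the risk set contributes `O` (observed HIGH
  events), `E = d·n_H/n` and the hypergeometric variance
  `v = d·(n_H/n)(1−n_H/n)(n−d)/(n−1)`. The hazard ratio is
  `exp((O−E)/V)`, its 95% CI `exp((O−E)/V ± 1.96/√V)`, and the two-tailed
  p comes from `(O−E)²/V ~ χ²(1)`. This O−E/V formulation was chosen over
  a Cox fit so that the per-cohort effect is exactly reproducible from the
  risk tables, matching how such HRs are reported by common GUI software.
  With a single covariate the Wald z of ln HR under this formulation
  coincides with the log-rank z, so only the χ² p is reported.
* **Continuous Cox model.** Single-covariate partial likelihood maximized
  by Newton iteration with step-halving (≤50 iterations), Efron tie
  handling by default (Breslow switchable; month-resolution data tie
  heavily, where Efron is the more accurate approximation). Monotone
  likelihood and non-convergence are flagged, not raised. Proportional-
  hazards diagnostics are deliberately out of scope; the model is used as
  an association summary only.

## Hazard-ratio meta-analysis

Per-study standard errors on the log scale are recovered from the reported
95% CI as `SE = (ln U − ln L)/3.92`, so pooling requires only the printed
per-cohort rows. Fixed-effects inverse-variance pooling is used
throughout: with only three cohorts, the between-study variance of a
random-effects model cannot be estimated stably, and all cohorts measure
the same disease and design. Weight percentages are reported rounded to
integers. The pooled CI upper bound follows mechanically from the pooled
SE; when checking against published tables only quantities that are
reproducible from the printed inputs are asserted.

P-values are pooled by weighted Stouffer Z with direction signs taken from
`sign(ln HR_i)`. The weight scheme is configurable (`sqrt-n` default, `n`,
or `inverse-variance`); √n weighting is the classical weighted-Stouffer
choice and reproduces the reference pooled p from the reference per-cohort
rows to within ~2%.

## Correlation meta-analysis

Spearman's ρ (midranks for ties; two-tailed p from the t-approximation on
n−2 df) is computed on pairwise-complete pairs, so the effective n — and
hence the n−3 weight — can differ between genes within one cohort. Fewer
than 4 pairs or zero rank variance yields a flagged missing result.
Coefficients of exactly ±1 have undefined Fisher-transform variance and
are excluded from pooling; near-unit values within 1e−12 of ±1 (float
noise on identical rank vectors) are snapped to ±1 and therefore excluded
too.

Pooling is on the Fisher z′ scale with weights nᵢ − 3, the reciprocal of
the large-sample variance of z′. The pooled standard error is
`1/√Σ(nᵢ−3)` — the square-root form, which is the dimensionally consistent
z′-scale SE and the analogue of the HR-side pooled SE. The 95% CI is
formed on the z′ scale and back-transformed endpoint-wise. Heterogeneity
per gene and stratum: Cochran's `Q = Σwᵢ(z′ᵢ − z̄′)²`, p from χ²(k−1), and
`I² = max(0, (Q−df)/Q)·100`. What is correlated is each candidate gene
against the marker within each stratum (gene-vs-gene pairs are possible
through the same API), reflecting the co-expression-network reading of the
design. No multiple-testing correction is applied across the panel; the
output carries raw pooled p-values and the panel is interpreted as a
curated hypothesis-generating set, not a screen.

## Δρ classification

`Δρ = ρ_high − ρ_low` on full-precision pooled values (never on rounded
output). Direction: |Δρ| < 0.29 Negligible, else by sign. Interpretation
bands are gated on `max(|ρ_low|, |ρ_high|) ≥ 0.3`, because correlations
below 0.3 are conventionally no/weak relationships and a difference
between two uninterpretable coefficients is itself uninterpretable. Band
edges are resolved as a partition: magnitudes in [0.29, 0.60) fall back to
"Independent correlation" (the band floor is 0.60), [0.60, 0.70) is the
lower band (the 0.60 boundary is closed), [0.70, 0.80) intermediate,
[0.80, 1.00] high; magnitudes above 1 are clamped into the high band with
a warning. Positive Δρ ≥ 0.60 through the gate carries the single
"Strengthened" label. These boundary choices reproduce every row of the
48-gene reference panel bundled in `stratmeta.reference`.

## Synthetic-data generator

The generator emulates the statistical structure the analysis consumes
and nothing more:

* **Marker:** Normal(10, 1) per sample — a log2-like expression scale;
  the analysis is unit-agnostic (ranks and a threshold).
* **Strata:** the generator applies the same trimmed-mean rule as the
  analysis, so generated stratum membership and recomputed membership
  agree exactly.
* **Candidate genes:** conditional on the realized stratum, gene = ρ·(stratum-
  standardized marker) + √(1−ρ²)·noise, then mapped to the expression
  scale by a monotone linear transform. Within-stratum Pearson correlation
  is exactly ρ; the Spearman value is attenuated by < 0.02 for |ρ| ≤ 0.5
  (no arcsine correction by default). The piecewise construction was
  chosen over a single global copula because the analysis measures the
  within-stratum contrast directly, which a global copula cannot target.
* **Survival:** exponential event times with hazard `h₀` (LOW) and
  `h₀·HR` (HIGH), independent exponential censoring, observation = min.
  Defaults: HR = 0.581 (the reference pooled effect), `h₀ = ln2/4 ≈ 0.173`
  events/month (a ~4-month median survival, typical of the disease — this
  also keeps natural >30-month survivors rare, so the window filter's
  right-truncation introduces negligible bias at the default rates),
  censor rate 0.02/month. A `window_contam_frac` (default 5%) of records
  is overwritten to 0 months or Uniform(30, 60) months purely to exercise
  the window filter. Survival is independent of gene expression given the
  stratum — the minimal structure the analyses require.
* **Determinism:** numpy PCG64 streams spawned per cohort from a single
  seed; identical seed ⇒ bit-identical study.

Not emulated: RNA-seq count distributions (negative binomial, library
size), batch effects, covariate-dependent censoring, or any direct
gene-survival coupling beyond the stratum. Passing calibration tests on
these data therefore validates the estimators and their wiring, not
robustness to those real-data features.

## Problem sizes in the test suite

Calibration tests run at the study's own scale (three cohorts of
143/142/112) where the target is a property of that design — pooled-CI
coverage of the true HR uses 500 replicate studies; the log-rank type-I
check uses 2000 two-arm null replicates of 50 per arm; Cochran's Q type-I
uses 1000 replicates of four 140-sample cohorts; generator self-checks
use single 5000-sample cohorts where only the targeting of the copula is
at stake. Mean pooled-correlation recovery averages 30 replicate studies,
trading replicate count against the ±0.1 recovery band.

## Known limitations

* The window filter is right truncation, not censoring; at survival scales
  much longer than the 30-month window the MH HR under this procedure is
  attenuated toward 1 relative to the generating HR.
* The MH HR is itself slightly biased for strong effects and unbalanced
  risk sets; the package mirrors the estimator as specified rather than
  replacing it with a Cox fit.
* Stouffer weights for the HR p-value pooling are a convention choice
  (√n default); the effect-size pooling is unaffected.
* Spearman p-values use the t-approximation, adequate for the stratum
  sizes here (≳ 50) but approximate for very small strata.
* The Fisher z′ variance 1/(n−3) is the bivariate-normal value; for
  Spearman coefficients the true variance is ≈ 6% larger, making Q and
  the pooled CI very slightly anti-conservative.
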