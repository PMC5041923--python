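# Methods

## Model and procedure

The pipeline pools published case-control genotype counts for one biallelic
SNP (risk allele G). Its assumptions are the standard ones of
aggregate-data genetic meta-analysis:

1. Within each study, cases and controls are independent samples from their
   populations and the 2×2 collapsed table is an unbiased estimate of the
   exposure-disease odds ratio for that population.
2. Control genotypes are in Hardy–Weinberg equilibrium; departure signals
   genotyping error or population stratification, so the control arm is
   screened with a 1-df goodness-of-fit χ² (no continuity correction) and a
   study is kept iff p > α. Only controls are screened — cases are expected
   to deviate from HWE when the variant is truly associated, so case-arm HWE
   is informational only.
3. Study log odds ratios θᵢ are approximately normal with known variance
   SEᵢ² (the Woolf estimate), and under the random-effects model
   θᵢ ~ N(θ, τ² + SEᵢ²) with τ² the between-study variance.

Per-study effects are cross-product ORs with Woolf SEs; pooling is
inverse-variance (fixed) and DerSimonian–Laird (random), with Cochran's Q,
I² and the moment τ² always computed from the *fixed-effect* weights. That
convention — heterogeneity from fixed weights even when the reported pooled
value is random-effects — matches mainstream meta-analysis software
(RevMan/metafor default) and is what makes the shipped fixture reproduce its
published I² values. The overall-effect test is a plain Wald z on the pooled
log OR; no Hartung–Knapp small-sample adjustment is applied, again matching
the software convention of the source analysis.

Three genotype collapsings are first-class: dominant (GG+TG vs TT),
recessive (GG vs TG+TT), and the homozygote-vs-heterozygote contrast
(GG+TT vs TG). The last is called "additive" throughout because that is the
label the source literature uses for it; it is *not* the conventional
allele-dose model. The conventional allelic 2×2 (G vs T allele counts) is
provided as `build_allele_contrast` but excluded from reproduction runs,
since the shipped fixture's published results use the three contrasts above.

Publication-bias output is funnel-plot data (log OR vs SE, inverted axis,
pseudo-CI guide lines pooled ± z·SE) plus Egger's regression of the
standardized effect on precision with a k−2 df t-test on the intercept.
Egger's test is an extension beyond the source analysis, which judged
funnels visually.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| `hwe_alpha` | 0.05 | probability | conventional screening threshold; keep iff control p > α (strict inequality) |
| `confidence_level` | 0.95 | — | CI level; the normal quantile is used at full precision (1.959964…), not 1.96 |
| `scheme` | random | — | random-effects is the conservative default when heterogeneity is present; fixed is always computed internally for Q/I² |
| continuity correction | +0.5 to all four cells | counts | Haldane–Anscombe, applied only when a cell is zero (never triggered on the fixture) |
| simulator `control_allele_freq_g` | 0.5 | probability | close to the fixture's control G frequency (~0.51) |
| simulator `or_het`, `or_hom` | 1.0, 1.0 | odds ratio | null model by default; effects are opt-in |
| simulator `tau` | 0 | SD of log OR | homogeneous by default |
| simulator arm sizes | 400/400 | individuals | typical of the mid-sized studies in the fixture |

## What the simulator emulates — and what it does not

Controls are multinomial draws from exact HWE proportions at allele
frequency p; case probabilities are the control probabilities re-weighted by
genotype-specific odds (TT baseline) and renormalized, which is
distributionally equivalent to logistic case sampling but much cheaper.
Between-study heterogeneity is one shared shift δᵢ ~ N(0, τ²) added to both
genotype log ORs, so a contrast whose exposure picks up the shift cleanly
(dominant when or_het = or_hom; recessive when or_het = 1) has study log OR
exactly baseline + δᵢ — precisely the structure DL pooling assumes. Useful
identities for tests: with or_het = 1, the collapsed recessive OR equals
or_hom exactly; with or_het = or_hom and τ = 0, the dominant OR equals that
common value.

Not emulated: population stratification, genotyping error, linkage with
neighbouring SNPs, covariate adjustment, or selective publication. Passing
coverage/type-I/τ²-recovery tests therefore demonstrates correctness of the
statistical machinery under the model's own assumptions, not robustness of
real meta-analyses to violations of them.

Per-study randomness comes from a substream seeded deterministically by
(seed, study_index), so datasets are reproducible and individual studies can
be regenerated in isolation.

## Numerical choices and degenerate inputs

* All computation is at full double precision; 2-decimal ORs/P and
  whole-percent I² appear only in display columns and the human summary.
* τ² and I² are truncated at 0; a single study gets Q = 0, df = 0, I² = 0
  with a logged note. When Q ≤ df, random-effects output equals
  fixed-effects output bit-for-bit (τ² = 0, identical weights).
* Monomorphic control arms (allele frequency 0 or 1) raise a
  degenerate-input error from the HWE test rather than returning 0/0.
* Zero cells raise from `odds_ratio` with instructions to apply the
  continuity correction; the pipeline applies it automatically.
* Egger's regression with all SEs equal has a constant predictor; the result
  is returned flagged `degenerate` with NaN statistics and a warning, so
  batch pipelines continue.
* Subgroups are pooled independently (each gets its own τ²); the overall
  result pools all studies jointly. A test for subgroup differences is not
  provided.

## Design notes

* The fixture's ethnicity split encodes the source's two-group ethnicity
  classification in the `subgroup` column of the CSV rather than in code;
  the library treats subgroup labels as free-form strings. The Fletcher
  (2008) study ("English and Scottish" participants) is assigned to the
  white-European group, consistent with the source's 6/3 split.
* The fixture's `reported_hwe_p` column carries the HWE p-values as
  published. Eight of nine agree with recomputation from the printed control
  counts to ±0.005; Fletcher (2008) does not (published 0.404, recomputed
  0.453 uncorrected χ², 0.476 exact). Those published values were extracted
  from the source studies, and Fletcher's original presumably tested a
  different or larger control sample than the counts tabulated here. The
  package always reports its own recomputed value; the discrepancy is
  asserted (and visible as a failing check) rather than patched over.
* Monte-Carlo test sizes (e.g. 500 replicates of k=20 studies at 2000/2000
  for CI coverage, 2000 replicates for HWE uniformity) were chosen so each
  check runs in seconds at desk scale while keeping the Monte-Carlo standard
  error well inside the asserted tolerance.

## Known limitations

* Aggregate-data only; no individual-level covariates or adjusted ORs.
* DL is the only τ² estimator (no REML/Paule–Mandel), and there is no
  Hartung–Knapp adjustment, meta-regression or trim-and-fill — deliberate,
  to match the convention of the analysis the fixture reproduces.
* The CSV schema fixes a single grouping column (`subgroup`); multi-factor
  subgrouping requires pre-relabelling.
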