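# Methods

## Setting and assumptions

The pipeline analyses a double-blind crossover supplementation trial: each
participant completes an EPA phase, a DHA phase and a control phase, so the
treatment response is a within-person contrast, ΔTG = post-supplementation
TG − post-control TG (mmol/l), one value per treatment. The analysis assumes
the control phase itself leaves TG unchanged and that carryover is handled
by the trial's washouts; neither is modelled here.

Genotypes are biallelic effect-allele dosages (0/1/2). The effect allele and
its scoring direction are fixed by the panel configuration — taken from the
discovery study's associations — and never re-estimated in the analysis
cohort. Re-estimating directions from the cohort under analysis would leak
outcome information into the score; keeping the panel definition fixed also
gives a stable orientation for SNPs whose "rare" allele drifts near or above
0.5 frequency in a new cohort.

## Genotype quality control

* **MAF** is the effect-allele frequency over non-missing participants
  (2 chromosomes each). Missing genotypes are excluded pairwise per SNP; no
  imputation of missing calls is done at QC level.
* **Hardy-Weinberg test**: 1-df Pearson chi-squared of observed genotype
  counts against n(1−p̂)², 2n·p̂(1−p̂), n·p̂² at the sample allele frequency
  p̂. Monomorphic SNPs return chi² = 0, p = 1 with a flag rather than an
  error. The filter drops SNPs with p < α (default α = 0.05, configurable);
  no multiple-testing correction is applied by default — a per-SNP 0.05
  screen matches the replication study's behaviour of excluding a single
  SNP from a 31-SNP panel. The statistic equals the square of the usual HWE
  z-statistic, √n·(p̂₂ − p̂²)/(p̂q̂), which the tests exploit as an oracle.
* **Cohort comparison**: per-SNP 2×2 allele-count table (effect/other ×
  cohort A/B), Pearson chi-squared with 1 df and no continuity correction.
  Continuity-corrected or exact alternatives are deliberately not applied;
  small-count behaviour is the analyst's responsibility, and the uncorrected
  statistic matches the published per-SNP comparisons this pipeline mirrors.
* **Rare-variant flag**: MAF ≤ threshold with an inclusive boundary
  (default 0.05). Inclusivity matters: the embedded panel contains a SNP at
  exactly 0.05 that is counted among the rare variants.
* The VCF reader maps REF/ALT onto the panel's other/effect alleles and
  raises on any mismatch instead of guessing strand flips.

## The signed rare-allele score

score = Σ over panel SNPs of direction × dosage, direction ∈ {+1, −1} from
the sign of the prior odds ratio (an OR of exactly 1 has no direction and is
rejected). This is *allele-count* weighting — a heterozygote contributes ±1
and a rare homozygote ±2 — not carrier status; "adding the rare alleles of
each participant" counts each copy. Effect-size magnitudes are deliberately
not used (unit weights only), and scores are not standardized.

Missing genotypes follow one of three policies: `skip` (default; the SNP
contributes 0 and is counted, and participants missing more than 20% of the
panel are flagged, never silently dropped), `strict` (error naming the
participant and SNP), or `mean_impute` (missing dosage ← 2×cohort MAF,
making scores non-integer). Under Hardy-Weinberg genotypes the score has
mean Σ 2·direction·MAF and variance Σ 2·MAF(1−MAF), which the tests use as
a closed-form oracle.

## Responder classification

The window half-width w is the cohort mean of per-participant sample SDs
(n−1 denominator) of repeated off-treatment TG measurements — the study used
4 repeats and obtained 0.25 mmol/l, which is the package default; a
cohort-specific estimate is available via `estimate_window`. Classification
is R if ΔTG < −w, AR if ΔTG > +w, NR otherwise: exact equality with the
boundary is non-response (the window is inclusive, matching "within the
window" for NR and "greater than" for R/AR). Post-phase TG may be a single
measurement or replicate measurements, in which case their mean is the
phase value; whether a study averages within-phase replicates is an input
convention, not something the package guesses.

## Association models

* **Ordinal**: proportional-odds cumulative-logit model, classes ordered
  R < NR < AR, fitted by maximum likelihood (statsmodels `OrderedModel`,
  logit link, BFGS with gradient tolerance 1e-10 and an L-BFGS fallback).
  The linear predictor enters as logit P(Y ≤ k) = t_k − x'b, so a positive
  GRS coefficient — OR = exp(β) > 1 — moves mass toward the adverse end.
  Age, sex (binary indicator, configurable reference level) and BMI are the
  default adjustment set.
* **Binary**: logistic regression of AR (=1) vs R (=0) after non-responders
  are excluded upstream; any unexpected label raises. Newton-Raphson with
  tolerance 1e-12.
* **Inference**: Wald tests on the ML standard errors, matching standard
  logistic-procedure output. Non-convergence flags the fit and warns rather
  than failing silently; curves refuse to draw from a non-converged fit.
  (Quasi-)complete separation raises a dedicated error, detected either from
  a singular/divergent Newton step or from coefficients exceeding 30 in
  absolute value on the log-odds scale.
* **Probability curves**: continuous covariates are held at sample means and
  sex at its observed proportion (a population-averaged curve is a
  reasonable alternative; the conditional-at-the-mean profile is the
  default and any profile can be supplied). 95% bands use the delta method
  on the linear predictor, then transform through the logistic link, so
  bands respect [0, 1]. The middle (NR) category is a difference of two
  link transforms with no single linear predictor; its band uses the delta
  method on the probability scale, clipped to [0, 1]. Threshold-parameter
  gradients account for statsmodels' log-increment threshold
  parameterization analytically. Grid points outside the observed GRS range
  are computed but flagged as extrapolation.
* A Brant-style common-slope diagnostic (separate binary fits per cumulative
  split, Wald test on the slope difference) is available but off by
  default: the proportional-odds assumption is a modelling choice of the
  replicated analysis, not something it tested.

One identity worth recording: for the intercept-containing *binary* logistic
model the ML score equations force the average fitted probability to equal
the observed class frequency exactly, and the tests assert this at 1e-9.
The analogous statement for the proportional-odds model with covariates is
only approximate — its threshold score equations weight observations by
f/L rather than summing fitted-minus-observed indicators — so the tests
check it at consistency level (5e-3 at n = 800), not as an identity. The
two-category ordinal model, however, reduces exactly to the binary model,
and the tests assert that equivalence at 1e-6.

## Synthetic-data generator

The generator is label-first: (1) genotypes are independent SNPs with
dosage ~ Binomial(2, MAF) — exact Hardy-Weinberg — with missingness
completely at random; (2) the true GRS is computed from the panel; (3) the
responder class per treatment is drawn from the proportional-odds model at
the configured cutpoints; (4) ΔTG is drawn from a normal truncated to the
drawn class's window interval (class-conditional means −0.5 / 0 / +0.5
mmol/l, SD 0.2 — invented plumbing, chosen to give clearly separated but
overlapping-looking response distributions); (5) post-control TG is a
truncated normal at the configured baseline marginals, constrained so every
post-treatment value stays positive with the drawn ΔTG preserved exactly;
post-treatment TG = control + ΔTG. This direction of generation makes
re-classification of the emitted TG values reproduce the drawn class with
probability 1, which the tests verify exactly. A continuous-ΔTG-first
variant is provided for sensitivity checks; its class frequencies do not
follow the latent ordinal model, so parameter-recovery claims do not apply
to it.

Off-treatment replicates (default k = 4) are drawn around each
participant's control level. Because the window statistic is the mean of
per-participant *sample* SDs and E[s] = c₄(k)·σ (c₄(4) ≈ 0.921), draws use
σ = intra_individual_sd / c₄(k): the `intra_individual_sd` parameter is
thereby defined as the expected mean observed SD — the quantity the study
actually reported — rather than the underlying normal σ.

Covariates are drawn once per participant: age ~ N(53.5, 14.7²) clipped to
18–70 years, sex ~ Bernoulli(0.5), BMI ~ N(29.3, 4.2²) clipped to 18–45
kg/m² — the cohort's published marginals. Default covariate effects on the
latent scale are zero.

The `study_like_preset` encodes the emulated study: n = 122 participants,
the 31-SNP panel at its published replication-cohort frequencies, baseline
TG 1.43 ± 0.71 mmol/l, intra-individual SD 0.25 mmol/l with 4 repeats, mean
treatment reductions 13.3% (EPA) and 18.9% (DHA), GRS effect log(1.2) per
unit. Cutpoints place the marginal class probabilities at
(R, NR, AR) = (0.45, 0.45, 0.10) at the mean linear predictor: the study
reports only the adverse-responder counts (9–12 of 122, ≈10%); the R/NR
split is not published, and an even split of the remainder is the neutral
choice. Per-SNP odds-ratio directions and allele bases were also never
published, so the built-in panel carries a fixed synthetic direction
pattern (about two thirds positive) and placeholder A/G alleles — suitable
for simulation and pipeline exercises, not for scoring real genotypes, and
labelled as synthetic where they are defined.

What the generator does **not** emulate: linkage disequilibrium between
panel SNPs (the score is additive, so independence is adequate for testing
it), population stratification, genotyping error, Hardy-Weinberg departures
(except planted ones in tests), within-phase TG replicate structure, and
treatment-order or carryover effects. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated generative model,
not robustness to those real-data complications.

## Numerical and reproducibility choices

* All randomness flows through `numpy.random.default_rng` seeded from the
  configuration; each generator stage uses an independent seed stream, and
  regenerating with the same configuration is bit-for-bit identical.
* Pipeline artifacts are written with 6-significant-digit fixed formatting
  and no timestamps, so reruns with identical config and seed diff
  byte-for-byte; the run log carries package versions, a config hash and
  per-stage counts instead.
* Monte-Carlo check sizes: parameter recovery uses 200 replicates at
  n = 2000 (ordinal, design OR 1.2) and n = 1000 (binary, design OR 2.3);
  calibration checks use 2000 simulations (HWE type-I at n = 500, Wald
  type-I at n = 500); window recovery uses one cohort of n = 500. These
  sizes put Monte-Carlo error well inside the tolerances they are checked
  against while keeping the default suite fast. At these sizes the expected
  first-order O(1/n) bias of the ML logistic estimator (≈+0.5% of β at
  n = 1000 under the preset design) is close to 2 Monte-Carlo standard
  errors of the 200-replicate mean; the recovery tests are therefore exact
  but deliberately seeded, and the mean recovered odds ratios are also
  reported by the acceptance script on the OR scale, where the deviation is
  ~1%.

## Known limitations

* No weighted GRS (effect-size magnitudes), no variance-explained
  decomposition, no SNP-by-SNP outcome modelling beyond the subgroup
  allele-frequency chi-squared comparisons.
* No LD computation: proxy SNPs are configuration data with their r²
  recorded as provenance.
* The allele-count chi-squared comparisons are asymptotic; with the rare
  SNPs of the embedded panel (MAF < 1%) expected cell counts are small and
  the printed p-values should be read as screening statistics.
* The ordinal model assumes proportional odds; the diagnostic is offered
  but no correction (partial proportional odds, multinomial) is
  implemented.
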