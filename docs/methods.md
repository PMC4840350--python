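# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limitations of `candigene`.

## Data model

Genotypes are unphased biallelic SNP dosages: for each sample and SNP the
number of copies (0/1/2) of a *counted* allele, with −1 marking a missing
call. `recode_to_minor` makes the counted allele the whole-sample minor
allele (cases and controls combined — the codings below are defined on the
minor allele and nothing downstream stratifies the definition); exact
frequency ties are broken toward the lexicographically smaller base so the
operation is deterministic and idempotent. Phase information in VCF input
is discarded: every downstream method (EM, logistic regression) assumes
unphased data. Chromosome labels are opaque strings compared by equality;
`normalize_chromosome` optionally strips a leading `chr`.

## Quality control

Per SNP: call rate, MAF, and the exact conditional HWE test. The HWE test
conditions on the observed allele counts; each attainable heterozygote
count *h* (same parity as the minor-allele total) has probability
proportional to `n! / (n_AA! n_Aa! n_aa!) · 2^h`, and the P value sums the
probabilities of all configurations no more probable than the observed
one. Probabilities are computed in log space (via `gammaln`) so
cohort-scale counts (tens of thousands) are stable. HWE is computed in
controls only — the field-standard choice for case-control QC, since true
risk variants can depart from HWE in cases. Defaults: MAF > 0.05,
HWE P ≥ 1e-4, call rate ≥ 0.97; a filtered matrix preserves SNP order.

## Single-marker association

Each SNP is coded additively (dosage), dominantly (0 vs ≥1 copy) or
recessively (2 copies vs rest) and entered in a logistic model with sex
and age (raw years) as optional covariates. Fits use a hand-written
Newton/IRLS maximiser with step-halving; Wald z = b/SE(b) against the
normal reference, CI at z = 1.959964. Missing genotypes are handled
complete-case per SNP. Quasi-separation is detected by coefficient blow-up
(|b| > 15 on the log-odds scale) and reported as a non-converged row; the
scan continues past failures. The unadjusted allelic test collapses
genotype counts to a 2×2 allele table (2N chromosomes per group) and
applies the 1-df Pearson chi-square without continuity correction; when a
cell is empty the OR gets a 0.5 continuity correction and is flagged.
Bonferroni thresholds are α/m.

The IRLS engine is cross-checked against `statsmodels.Logit` in the test
suite; it exists (rather than delegating to statsmodels) because the
permutation epistasis scan refits hundreds of small models per shuffle and
needs a vectorised batch fitter.

## LD and Gabriel blocks

Two-SNP haplotype frequencies come from EM over the single ambiguous class
(double heterozygotes), started at linkage equilibrium, iterated to a
max-change of 1e-9 (cap 1,000 iterations). D = f_AB − p_A·p_B; D′ = |D| /
D_max with the standard sign-dependent bound; r² = D² / (p_A p_a p_B p_b).

The 95% bounds on D′ follow the Haploview-style approximation: the
multinomial likelihood of the observed two-SNP genotype table is evaluated
on a D′ grid (step 0.01, 0 to 1) with allele frequencies held at their
MLEs and the sign of D fixed at its MLE; after normalisation, the lower
bound is the largest grid value with at most 5% of the likelihood mass
strictly below it and the upper bound the smallest grid value holding at
least 95% at or below. This construction makes the bounds monotone by
cumulative sum, so `ci_low ≤ ci_high` always. Full joint profiling of the
allele frequencies is deliberately out of scope.

Pairs are classified per Gabriel et al.: strong LD when
`ci_high ≥ 0.98 and ci_low ≥ 0.7`; recombination when `ci_high < 0.9`
(the Gabriel/Haploview convention for the historical-recombination bound);
otherwise non-informative. Candidate blocks are contiguous runs (≥ 2 SNPs,
one chromosome) whose outermost pair is strong LD, accepted when at least
one comparison is informative and the strong fraction among informative
comparisons is ≥ 0.95; accepted greedily longest-first (ties to the
leftmost start), skipping overlaps. The population-specific spacing rules
of the original block definition are omitted — the intended panels are
sparse tag SNPs (~4 per gene region), where they never bind.

## Haplotype association

Within a block, multi-SNP haplotype frequencies come from EM over all
phase resolutions of each multilocus genotype (individuals missing any
member SNP are dropped; blocks wider than 12 SNPs are refused — the
enumeration bound). Initialisation is at products of allele frequencies;
convergence at max frequency change < 1e-6, cap 5,000 iterations.
Haplotypes with numerically extinct frequencies (< 1e-9) are dropped;
those below the pooling threshold (default 0.01 overall) are merged into a
`RARE` class. Case (F_A) and control (F_U) frequencies are
posterior-weighted counts within each status group under the
pooled-sample EM solution. Tests treat expected haplotype counts as
observed — the standard toolchain convention; the extra EM variance this
ignores is a known approximation that slightly overstates significance
when phase is very ambiguous. Per-haplotype tests are 2×2 Pearson
chi-squares (target vs rest, case vs control); the omnibus test is the
H×2 Pearson chi-square with H−1 df.

## Epistasis

For every SNP pair on distinct chromosomes (and only those — same-
chromosome pairs confound interaction with LD), the model
`logit P(Y=1) = b₀ + b₁g₁ + b₂g₂ + b₃g₁g₂ (+ sex + age)` is fitted with
additive codings at both loci and the interaction judged by the Wald test
on b₃ (OR_int = exp b₃). Main effects b₁, b₂ are reported for diagnostics
but not tested against the permutation null.

Family-wise error over the pair family is controlled by max-statistic
permutation: case-control labels are shuffled against the joint
(genotype, covariate) rows — preserving genotype-covariate linkage and the
exact case/control totals while breaking status-covariate association —
and each replicate records the most significant nominal P across pairs.
The corrected P of a pair is `(1 + #{min P ≤ observed}) / (1 + n_perm)`
(add-one form, so no corrected P is exactly zero; the floor at 1,000
permutations is just below 0.001). Non-converged fits contribute no min-P
candidate. All fits — observed and permuted — use one vectorised batch
Newton solver over stacked per-pair designs, which is what makes
thousand-permutation scans practical.

A 3×3 genotype-combination summary (percentage of cases per two-locus
dosage combination, with marginals and the overall case percentage) is
provided for inspecting significant pairs; empty cells are reported as
missing, not zero.

## Meta-analysis and power

Per-study log odds ratios are pooled by inverse-variance weighting (fixed
effect), with Cochran's Q and I² = max(0, (Q − (k−1))/Q); the
random-effects model uses the DerSimonian-Laird moment estimator
τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)) and weights 1/(SE² + τ²). With
τ² = 0 or a single study the two models coincide. Study SEs may be given
directly or recovered from symmetric log-scale 95% CIs at z = 1.959964.
Both pooled estimates are always reported side by side, since published
summaries often do not say which model produced a pooled OR.

Power of the two-sided 1-df allele-count test uses the normal
approximation: the case allele frequency derives from the control MAF and
the per-allele OR through the odds transform
(`odds_case = OR·p/(1−p)`), the standardized difference uses binomial
variances at 2N chromosomes per group, and power = Φ(|Δ|/SE − z_{1−α/2}).
At OR = 1 the function returns α (the size) by convention. No prevalence
modelling is attempted; a Monte-Carlo companion (`simulate_power`) draws
allele-count tables and agrees with the analytic value to within 0.02 in
the tested regimes. For the built-in design (2,518/7,521, MAF 0.3,
α = 0.001) analytic power is 0.97 at OR 1.2 — comfortably above the 80%
design target for effects in the 1.2–1.3 range.

## Synthetic cohort generator

The generator emulates a candidate-gene study design, and its defaults are
the study conditions every simulation-based test uses:

- **Panel**: 35 tag SNPs in 8 gene regions over 4 chromosomes with
  per-chromosome counts (12, 12, 8, 3) for chromosomes 17, 19, 16, 22 —
  the split that yields exactly 432 cross-chromosome pairs
  (C(35,2) − ΣC(n_c,2) = 595 − 163). The exact within-chromosome
  distribution beyond this constraint is a fixture choice.
- **Haplotype pools**: per region, a first-order Markov chain across SNPs
  couples minor alleles of adjacent pairs at D = ld_level·D_max, so
  marginal MAFs hit their targets exactly and adjacent D′ equals the
  requested level (default 0.95; 1.0 with equal MAFs collapses to a
  two-haplotype pool). Target MAFs cycle through a fixed grid in
  [0.12, 0.45], satisfying the panel constraints MAF > 0.05 and
  heterozygosity > 0.2.
- **Cohort**: 2,518 cases / 7,521 controls; age from a truncated normal
  (mean 37.6, SD 9.5, range 18–51, integer years); sex Bernoulli with
  female fraction 0.52; genotype missingness 0.5% (call rate 99.5%)
  injected independently per entry.
- **Disease model**: prospective logistic sampling with quota retention —
  individuals are drawn, status is Bernoulli in the logistic model
  (intercept default logit(2518/10039); per-allele main effects;
  additive×additive interaction effects; optional sex/age effects, zero by
  default since no covariate effect sizes are part of the design), and
  sampling continues until both quotas are filled. Case-control
  ascertainment of a logistic model preserves all odds ratios except the
  intercept, which is why downstream fits recover the generating effects.
  A pathological intercept that cannot fill the quotas raises an error
  suggesting adjustment.
- **Randomness**: one integer seed feeds `numpy.random.SeedSequence`,
  which spawns independent streams for haplotype draws, age, sex, status
  and missingness — each stage is separately reproducible.

What the generator does *not* emulate: recombination maps, mutation,
population structure or admixture, relatedness, batch effects, and
genotyping-error-driven HWE departures. Passing tests therefore
demonstrate correctness of the estimators and error control under a clean
random-mating model, not robustness to confounding — in particular,
population stratification (uncorrectable in small candidate panels) would
inflate type-I error in real data exactly as it would in any association
toolchain.

## Problem sizes used in tests

Simulation-based checks choose sizes by what each property needs:
parameter-recovery checks run at the full design size (10,039 samples,
20 replicates) because bias and CI coverage are the point; the
family-wise-error calibration of the permutation scan uses 100 reduced
null studies (600 samples, 12 SNPs in four 3-SNP regions on two
chromosomes, 200 permutations) since FWER calibration is invariant to
these reductions; oracle-agreement checks (EM vs exhaustive-phase
maximisation, exact HWE vs rational-arithmetic enumeration) run at n ≤ 30
where the oracles are exact.

## Known limitations

- The D′ CI is a profile approximation (allele frequencies fixed at
  MLEs); bounds can be slightly anticonservative at small n.
- Haplotype tests ignore EM uncertainty (expected counts treated as
  observed).
- The logistic interaction coefficient has the usual O(1/n) MLE bias when
  double-homozygote cells are sparse; at candidate-gene sample sizes with
  common alleles this is negligible, at small n it is visible.
- No X-chromosome handling, no multi-allelic variants, no imputation or
  dosage input, no stratification correction.
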