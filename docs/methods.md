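# Methods

This note documents the statistical machinery, the choices made where the
design was genuinely open, the synthetic-data generator's calibration, and
what the test suite does and does not establish about real data.

## Survival engine

**Cox regression.** The partial likelihood is maximised by Newton iteration
with step-halving, to a gradient-norm tolerance of 1e-8 (max 100 iterations);
the covariance estimate is the inverse observed information at the optimum.
Both the Efron (default) and Breslow tie corrections are implemented; Efron
is the less-biased standard under ties, Breslow is retained because the
two-group log-rank statistic equals the Cox score test under Breslow ties,
which the tests exploit as an internal consistency oracle. Degenerate inputs
fail loudly: zero events, a constant covariate, or a monotone likelihood
(perfect separation, detected either as a diverging coefficient during
iteration or a converged coefficient beyond ±10 paired with a standard error
above 1e3) raise errors naming the offending covariate. The baseline hazard
is never estimated — no output of the pipeline needs it.

**Wald summaries.** All hazard ratios, confidence intervals, z-scores and
p-values are computed on the log-hazard scale: `z = β/se(β)`,
`HR = exp(β)`, `CI = exp(β ∓ 1.959964·se)`, `p = 2(1 − Φ(|z|))`. Published
interaction z-scores are reproducible from printed iHRs and CIs by the same
formula (`z_from_printed_ci`), which is how the package cross-checks the
published screening table: the interaction z is the Wald statistic of the
log interaction coefficient, not the ratio of the iHR to its own standard
error, which would not reproduce the printed values.

**Kaplan–Meier and log-rank.** Product-limit estimation uses the standard
events-before-censorings convention at tied times; variance is Greenwood's.
Fixed-horizon confidence intervals use the log(−log) transform, which
respects the [0, 1] range and matches the asymmetric intervals typical of
published survival summaries. The median is the earliest time at which the
survivor function reaches 0.5 or below, with an explicit not-reached state
(`None`) that propagates through median differences. The two-group log-rank
test is the usual hypergeometric O−E statistic on 1 df.

## Interaction screening

Each binary feature is tested in its own three-term model
(treatment, gene, treatment×gene); arm is coded TKI = 1, chemo = 0, so a
negative interaction z means the alteration shifts relative benefit toward
TKI. Features altered in fewer than `min_altered` patients (default 10,
just below the smallest published signature marker at n=12) are reported
SKIPPED rather than unreliably fitted; fits that fail or diverge are
reported FAILED. Selection uses raw p < 0.05 by default, matching the
original analysis; Benjamini–Hochberg correction is available as an option
for methodological comparison, never as the default. Clinical adjustment
(age, sex, smoking, stage, N stage) enters as main-effect terms with
categorical covariates expanded to indicators; constant covariates are
dropped with a warning. The prognostic test is the treatment-adjusted model
without the interaction term, reading off the gene main effect.

Feature *combination* (e.g. merging RB1 mutations with RB1 copy-number loss,
or TP53 exon 4 with exon 5 missense) is declarative through
`FeatureDefinition` rules; the package never auto-merges marginal features —
those merges are scientific judgment calls, so the artifact only makes a
proposed merged feature testable.

Univariate (marginal) screening estimates marginal interaction effects.
When several markers act simultaneously, these differ from the conditional
per-marker effects by Cox non-collapsibility: the recovery harness shows a
systematic attenuation of order 0.15–0.2 on the log scale under the default
five-marker generator, and essentially zero bias when the generator carries a
single marker (where the fitted model matches the truth). This mirrors how
such screens behave on real cohorts and is why the recovery acceptance
checks use single-marker generators.

## Composite score and stratification

The score is the linear combination of 0/1 alteration indicators weighted by
interaction z-scores. A wild-type patient scores exactly 0; weighted
features missing from a cohort's matrix are treated as wild-type with a
warning (an external cohort may simply lack calls for a gene). Cutoff
boundaries are inclusive toward the outer groups — HTP includes −0.5 and CP
includes 0.5 — following the published subgroup definitions; no subset sum
of the five published weights lands exactly on ±0.5, so this matters only
for refit signatures. The six patients co-altered for NKX2-1 and RB1 score
2.88 − 2.72 = 0.16 and fall in TP under the plain cutoff rule; no special
case is needed.

Candidate cutoff evaluation is report-only: for each pair it tabulates
subgroup sizes, within-subgroup log-rank statistics, and a *separation*
statistic defined as the subgroup-size-weighted mean of |log within-subgroup
treatment HR|. The criterion by which the original cutoffs were chosen is
not fully specified, so this statistic is an explicit, documented stand-in
and the function never auto-selects a winner. The degenerate pair (c, c) is
handled as a two-group split (TP empty) and flagged.

Benefit metrics per subgroup: KM survival at a configurable horizon (default
24 months) per arm and their TKI/chemo ratio; medians per arm and their
difference with not-reached propagation; the treatment HR from a
treatment-only Cox fit; and the two-group log-rank p. If every chemo
patient in a subgroup fails before the horizon the ratio is +inf (the
direction is well-defined); aggregates over repeats average finite ratios
and count infinities separately.

## Cross-validation

Ten-fold CV stratifies fold assignment by treatment arm so every training
split contains both arms (interaction models are not identifiable in a
single-arm split); a partition that leaves an arm event-free in some
training split is resampled with a flag. Within each fold the screen runs on
the training 90% under the same selection rule as the full-data signature,
and the held-out 10% are scored with the in-fold interaction z weights — a
held-out patient's own alterations can never influence their own score. An
empty in-fold selection scores its held-out patients 0 (the wild-type
value) so every patient is classified in every repeat. After the folds,
the complete set of mock scores is classified, per-subgroup benefit is
computed, and the mock score is tested as a continuous treatment-interacting
covariate. All randomness derives from one seed through per-repeat
`SeedSequence` spawn keys, making reruns bit-identical. LOOCV applies the
same selection rule leaving one patient out at a time and is fully
deterministic; degenerate training sets (the left-out patient was an arm's
sole member) score 0 with a warning.

Aggregate statistics report means and standard errors over repeats, with
not-reached medians and undefined ratios excluded and counted. The fraction
of repeats whose mock-score interaction reaches p < 0.05 / p < 0.1 is
reported over the repeats where the test is defined.

## Synthetic cohort generator

The generator draws binary features independently at configured prevalences
(with an optional pairwise joint-prevalence adjustment, e.g. to reproduce
NKX2-1/RB1 co-occurrence), then event times from an exponential or Weibull
baseline scaled by `exp(ψ1·r + Σψ2·g + Σψ3·r·g)`, under administrative
censoring: uniform accrual over a window against a fixed database-lock
horizon, with optional independent exponential dropout (off by default).
Overall survival is the latent event time plus an exponential
post-progression tail, the simplest mechanism guaranteeing OS ≥ DFS; OS
analyses are structural, not calibrated. Arm assignment allocates exactly
`round(n·arm_probability)` patients to TKI, reproducing the 95/76 split at
n=171. Alteration rows are emitted in call classes that map back to the
named features (copy-number features as CN_gain/CN_loss calls, TP53 exon 4/5
as missense calls on those exons, RB1 as a mix of mutation and CN-loss
calls) with quality fields that pass the variant filters, so generated
tables round-trip the full io layer.

**Default calibration.** The emulated cohort fixes what is reported: n=171
with 95/76 arms, prevalences 33, 34, 12, 29, 15 of 171 for RB1_alt,
NKX2-1_gain, CDK4_gain, TP53_e45_mis and MYC_gain, and interaction log-HRs
ln(4.07), ln(0.26), ln(0.14), ln(0.33), ln(0.10). The remaining parameters
are unrecoverable from published summaries and are package calibrations,
chosen once and overridable:

- treatment log-HR ln(0.60) — the trial-level DFS advantage of TKI;
- exponential baseline with a 21-month chemo-arm wild-type median;
- gene main effects +0.75 for the four TKI-favoring markers and −0.35 for
  RB1, so chemo-arm marker-positive medians loosely track the printed ~9 and
  ~34 month chemo medians of the outer subgroups;
- accrual 30 months against a 60-month horizon, yielding a pooled DFS event
  fraction of roughly two thirds (≈0.73 at n=171, seed 0).

Clinical covariates (age, sex, smoking, stage, N stage) are drawn with
plausible marginals and are independent of features and survival by default;
confounded scenarios for testing are constructed explicitly in the tests.

**What the generator does not emulate:** the 422-gene mutation spectrum
beyond the five markers (optional uniform-prevalence decoys stand in for
nuisance features), non-proportional hazards, informative censoring,
within-patient correlation of marker effects with clinical covariates, and
any sequencing-read-level structure. Passing tests therefore demonstrate
that the pipeline's statistics behave correctly under the proportional-
hazards structure the method assumes — not that the published cohort-level
estimates would be reproduced on the restricted real data. The real-data CV
fractions (75% of repeats at p < 0.05) and the exact subgroup sizes are in
that sense out of reach by construction; the tests check directions,
calibration and contracts instead.

## Numerical and interface choices

- Exon numbers are gene-local, 1-based, taken at face value from annotated
  input; no transcript mapping or genomic coordinates are handled.
- Copy-number events arrive as categorical gene-level calls; no thresholds
  on copy-number values are applied.
- Variant filters implement the post-calling rules (recurrence-dependent
  VAF/supporting-read minimums, depth ≥ 20, base quality ≥ 25, strand bias
  ≤ 10%, population frequency ≤ 1%, panel-of-normals rate ≤ 20%); strict
  mode (default) rejects small-variant calls missing a required quality
  field, lenient mode drops them with a count.
- Patients absent from the alteration table are scored all-wild-type with a
  logged count; calls for unknown patients warn and are ignored (or raise,
  configurably).
- Problem sizes in the test suite (n=4000 with 100 replicates for recovery,
  60 null cohorts at n=1000 for calibration, 100 CV repeats at n=171) were
  chosen to make Monte-Carlo bands tight relative to the assertions while
  keeping the whole suite around two minutes on one CPU.

## Known limitations

- The Wald interaction test is slightly anticonservative at very small
  per-cell event counts; `min_altered` is a blunt guard, not a fix.
- Refit weights are selection-conditioned (only features passing p < 0.05
  get weights), so refit signatures inherit winner's-curse inflation at
  small n — visible in the recovery harness at n=171.
- The separation statistic used to rank cutoffs is one reasonable choice
  among several; rankings near ties should not be over-interpreted.
- `evaluate_cutoffs` and `benefit_summary` treat subgroups independently;
  no multiplicity control is applied across subgroups.
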