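# Methods

## Scientific setting

The package analyzes experience-sampling data of the kind produced by
the Electronically Activated Recorder (EAR): a wearable device records
a 30-second ambient audio clip every 12.5 minutes during waking hours
(06:00–24:00) for 72 hours, and trained coders mark each clip for a
roster of everyday behaviors. The scientific question is whether a
standardized psychometric trait composite — here a life-history-strategy
battery whose seven scale z-scores are averaged into a single K-factor
score — predicts how often each behavior occurs.

Counts, not proportions, are the unit of inference: a participant with
60 multi-speaker clips out of 120 social clips carries more information
than one with 10 of 20, and converting to proportions discards the
denominator. Each behavior therefore has a denominator rule defining the
clips in which it *could* have occurred (clips recorded 06:00–18:00,
clips awake, clips in social interaction, weekday 08:00–17:00 clips, or
clips in which the participant speaks).

## The model

For participant–stratum row *i* with *k_i* occurrences out of *n_i*
eligible clips:

```
k_i        ~ Binomial(n_i, p_i)
logit(p_i) = α + a_PARTICIPANT[i] + Σ_j β_j x_ij
α, β_j     ~ Normal(0, 2)
a_p        ~ Normal(0, σ)
σ          ~ HalfCauchy(0, 1)
```

Predictors are a weekend dummy (17:00 Friday through 24:00 Sunday,
taken from the aggregation stratum), a sex dummy (female = 1), and the
z-scored trait composite. Aggregation is stratified by weekend at
aggregation time because a clip-level dummy can only be carried into an
aggregated binomial likelihood through strata with constant covariates.
The trait score is standardized over the participants entering each
design, so the intercept refers to a participant at the mean trait
value. The binomial coefficient is included in the likelihood: it is
irrelevant to inference but required for pointwise WAIC terms to be
comparable across models of the same rows. Rows with n = 0 carry no
information and are dropped (counted in the fit metadata).

Partial pooling is the point of the hierarchy: participant intercepts
far from the grand mean, or based on few eligible clips, are shrunk
toward it, which test `test_small_denominator_offset_shrinks_harder`
verifies directly.

## Sampling

The posterior is explored with an in-package adaptive
Metropolis-within-Gibbs sampler (`earlife.sampler`), vectorized across
chains. Plain MWG mixes poorly here because of three posterior ridges,
each of which gets a dedicated move:

1. **σ–offset coupling** — an ancillary, non-centered move rescales all
   offsets by σ′/σ while proposing σ′, holding offsets/σ fixed;
2. **α + mean(offset)** — the likelihood cannot separate the intercept
   from a common shift of all offsets; a translation move slides along
   this direction and is accepted on the prior ratio alone;
3. **participant-level slopes** — for covariates constant within a
   participant (sex, trait), β_j is likewise identified only through
   the offset prior; an analogous translation move handles it.

Proposal scales adapt by Robbins–Monro toward 0.44 acceptance during
warmup and are frozen afterwards. Defaults are 4 chains × 2,000 draws
after 1,000 warmup iterations; convergence is summarized with split
R-hat (≤ 1.01) and bulk ESS (≥ 400) via ArviZ, and misses attach a
`ConvergenceWarning` and set `converged=False` rather than failing.
Reduced profiles (tests, permutation batches; e.g. 2 × 500) relax the
thresholds to R-hat ≤ 1.05 / ESS ≥ 100, since an ESS of 400 is
unreachable from 1,000 retained draws regardless of mixing quality.
Degenerate σ ≤ 0 proposals are rejected states (log-posterior −∞), not
exceptions.

## Model comparison and selection

WAIC is computed from the pointwise posterior log-likelihood over
aggregated rows: `lppd_i = log mean_s exp(ll_is)`,
`p_i = Var_s(ll_is)` (population variance over draws, the ArviZ
convention), `WAIC = −2 Σ_i (lppd_i − p_i)`. Akaike weights are
normalized `exp(−½ ΔWAIC)`. The standard error from the pointwise
spread is reported but not used in selection.

Selection mirrors the study workflow: weekend-only and sex-only models
are screened one at a time against the intercept-only null, and a
nuisance covariate is adopted only when its 95% credible interval
excludes zero *and* its pairwise Akaike weight exceeds the null's
(both-required, with each criterion exposed separately as flags). The
trait model plus adopted nuisances is then compared pairwise against
the nuisance-only reference. Class attendance — possible only on
weekdays — skips the nuisance screen and is compared against the
intercept-only model. Credible intervals are central 95% percentile
intervals; `summarize(sample, prob=0.93)` provides the 93% variant.

## Permutation multiplicity check

For each trait-favored behavior, trait scores are reassigned uniformly
at random among participants (identity permutation allowed, multiset
preserved), everything else held fixed, and the trait model is refitted
— 100 runs at study scale, 25 in the scaled-down profiles. The
trait-free reference model is fitted once and shared across runs. The
report counts runs whose |slope| or weight reaches the real data's and
tallies runs attaining ~full weight (≥ 0.995, i.e. 1.00 at two
decimals) in each slope direction with their median slopes.

## The synthetic generator

The generator emulates the study's observation process so every stage
is testable without the original recordings:

* **Schedule** — one slot per 12.5 min, 06:00–24:00, timer restarting
  daily (87 slots/day, 261 per participant), start weekday uniform on
  Monday–Friday; enumerating start days gives a weekend-clip fraction
  of 363/1305 ≈ .278.
* **Compliance** — i.i.d. per clip at 232/261.
* **Sleep** — a latent day-level process: the daily sleep fraction in
  06:00–18:00 follows the daytime-sleeping logistic model and is
  realized as a late rise (Beta(4,2) share) plus one afternoon nap, so
  asleep clips form runs as in real EAR data rather than i.i.d. coin
  flips.
* **Behaviors** — conditionally independent Bernoulli clips given the
  participant intercept, drawn only inside each behavior's denominator;
  speaking occurs in 90% of social clips and 5% of awake solitary ones.
* **Codability** — per behavior, ~a third of participants lose
  floor(U(0, .066)·n) of their eligible clips to an "uncodable" code,
  respecting the study's 6.6% maximum by construction.
* **Cohort flags** — 4 participants not enrolled in classes, 1 without
  early-morning data, reproducing the 91→87 and 91→90 filters.
* **Trait battery** — seven equicorrelated scale scores with
  inter-scale correlation r = .68/(7 − .68·6) ≈ .233, so Cronbach's
  α across scales ≈ .68; the composite is their re-standardized mean.

Generating parameters default to the study conditions: weekend, sex,
and trait slopes are the published posterior means (the internally
inconsistent daytime-sleeping weekend entry is taken as 1.07, the value
consistent with its printed interval). Because published intercepts are
shrunken posterior summaries, the generating intercept and
random-intercept SD are instead solved jointly — Gauss–Hermite
quadrature of the logistic-normal moments of participant proportions,
including binomial noise at realistic denominators — so that simulated
cohorts reproduce the published mean *and* SD of per-participant
occurrence proportions. These values were fixed once from that
calibration and are not tuned.

What the generator does **not** emulate: serial dependence of behaviors
within a day beyond sleep, situational drivers of behavior, school
holidays (a holiday flag is accepted on input but never generated),
participant-initiated clip deletion, and coder drift. Passing tests
therefore show that the pipeline recovers parameters and controls false
positives under the model's own exchangeability assumptions at the
study's size and effect scale — not that those assumptions hold in real
EAR data.

## Numerical choices and degenerate inputs

* Aggregated binomial log-density is computed with `log_expit` on both
  tails, so |η| up to hundreds stays finite; structural 0·(−∞) limits
  (k = 0 with p → 0, k = n with p → 1) are defined as 0.
* Cohen's κ returns 1 when both raters are constant and identical
  (p_e = 1), where the raw formula is 0/0.
* Timestamps are clip start times; all time-window predicates are
  half-open [start, end).
* Merged religious+volunteer counts: clip-level union when clips are
  available (a clip with both behaviors counts once), else k₁+k₂ capped
  at n; mismatched denominators are an error, zero-denominator merges
  warn and are retained.
* All randomness flows from explicit seeds through
  `numpy.random.SeedSequence` spawning; identical seed and
  configuration reproduce every output bit-for-bit, MCMC included.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run one synthetic cohort at
full study size (91 participants, ~21,000 scheduled clips), single-fit
checks at 2 chains × 700–800 draws, replication studies (parameter
recovery, null calibration) at 20 and 15 cohorts with 2 × 300–400
draws, and permutation batches of 25 runs — sizes chosen so the whole
pipeline demonstrates its properties in minutes while the defaults
(4 × 2,000 draws, 100 permutation runs) remain the analysis settings.

## Known limitations

* The sampler is a random-walk scheme; for much larger cohorts or many
  more predictors a gradient-based engine would scale better (the
  log-posterior is exposed for exactly that kind of cross-check).
* WAIC standard errors are reported but unused; no LOO-CV.
* No random slopes, non-logit links, zero-inflation, or clip-level
  serial-dependence models — matching the analysis this package
  implements.
* Published κ values are inputs, not reproduction targets: the original
  coder test set is unavailable, and the paper does not state how
  kappa was aggregated over its 11 raters (mean pairwise is assumed).
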