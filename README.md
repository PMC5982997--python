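# earlife

Bayesian analysis of EAR behavior-count data: does a psychometric
life-history-strategy composite predict how often everyday behaviors
occur?

The Electronically Activated Recorder (EAR) samples daily life as brief
periodic ambient audio clips — here one 30-second clip every 12.5
minutes between 06:00 and 24:00 over 72 hours — which coders mark for
behaviors such as social interaction, class attendance, daytime
sleeping, or being at a bar or concert. Each behavior yields, per
participant, a count *k* of clips containing it out of *n* clips in
which it could have occurred (its denominator: awake clips, clips in
social interaction, weekday 08:00–17:00 clips, ...). `earlife`
implements the full analysis pipeline for such data:

* a **synthetic data generator** emulating the sampling protocol
  (compliance, blackout hours, weekend structure, latent sleep runs,
  codability dropout) with known ground-truth parameters;
* **aggregation** of clip records into participant × weekend-stratum
  count tables under the per-behavior denominator rules, cohort
  filters, and the merging of the two rare prosocial behaviors;
* **reliability screening** with Cohen's κ (mean pairwise over raters)
  and the preregistered κ < .41 exclusion gate;
* the **multilevel aggregated binomial regression**

  ```
  k_i ~ Binomial(n_i, p_i)
  logit(p_i) = α + a_PARTICIPANT[i] + Σ β_j x_ij ,
  α, β ~ Normal(0, 2),  a_p ~ Normal(0, σ),  σ ~ HalfCauchy(0, 1)
  ```

  fitted with an in-package adaptive MCMC sampler (vectorized chains,
  ancillary non-centered moves, split R-hat / bulk-ESS diagnostics);
* **model comparison** via WAIC and Akaike weights, with the two-step
  nuisance-screening (weekend, sex) and trait-model selection workflow;
* a **permutation multiplicity check** that reassigns trait scores
  among participants and refits, comparing real slopes and weights to
  the permutation distributions.

See `docs/methods.md` for the model, sampler, calibration of the
generator, and known limitations; `docs/count_table_schema.json`
documents the on-disk count-table columns.

## Worked example

```python
import earlife
from earlife import ModelSpec, SamplerConfig, fit, summarize

# one synthetic cohort at the study's conditions: 91 participants,
# ~232 compliant clips each, known ground truth
clips, participants, truth = earlife.simulate_study(n_participants=91, seed=1)
rows = earlife.aggregate_counts(clips, list(earlife.analyzed_behaviors()))
rows = earlife.merge_religious_volunteer(rows, clips=clips)
rows = earlife.apply_cohort_filters(rows, participants)

print(earlife.run_descriptives(rows).loc[
    ["daytime_sleeping", "social_interaction", "amusement_venue"]])

sample = fit(
    ModelSpec("social_interaction", ("weekend", "alhb")),
    rows[rows["behavior"] == "social_interaction"],
    participants,
    SamplerConfig(chains=2, draws=800, warmup=800),
    seed=2,
)
print(summarize(sample))
```

prints

```
                    n_participants  mean    sd   min   max  prop_engaged
behavior
daytime_sleeping                90 0.286 0.141 0.040 0.706         1.000
social_interaction              91 0.351 0.170 0.047 0.872         1.000
amusement_venue                 91 0.014 0.028 0.000 0.158         0.615

               mean    sd  ci_low  ci_high
parameter
alpha        -0.890 0.087  -1.049   -0.721
beta_weekend  0.615 0.045   0.530    0.699
beta_alhb     0.195 0.086   0.024    0.368
sigma         0.821 0.067   0.693    0.956
```

Reading the output: participants engage in social interaction in ~35%
of their awake clips; the behavior is more frequent on weekends (log-
odds +0.62, the generator's true value), the trait slope is recovered
near its generating value of 0.19, and σ ≈ 0.8 is the spread of
participant-specific intercepts on the log-odds scale. `mean ± sd`
columns in the descriptives are per-participant occurrence proportions;
`prop_engaged` is the fraction of participants observed to do the
behavior at least once. The intercept corresponds to a weekday clip of
an average-trait participant: `inverse_logit(-0.89) ≈ .29`.

The same stages are scriptable from the shell:

```bash
earlife simulate --participants 91 --seed 1 --out data/
earlife aggregate --clips data/clips.csv --out data/counts.csv
earlife report --counts data/counts.csv
earlife compare --counts data/counts.csv --behavior amusement_venue --seed 3
earlife run-all --seed 1 --out results/
```

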