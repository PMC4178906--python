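# Methods

## Scoring engine

The instrument is an ordered interval ("band") lookup per vital sign plus a
sum of social items. Three conventions close the gaps a printed table
leaves open:

* **Rounding.** Measurements are rounded half-up to the precision at which
  the bands are printed: whole units for respiratory rate, heart rate,
  systolic pressure and SpO₂; one decimal for temperature (so 37.95 °C
  becomes 38.0 and scores 1). Half-up (not banker's) rounding is used
  because that is how printed clinical tables are read.
* **Gap rule.** After rounding, any value still uncovered by a band is
  assigned to the adjacent band with the *higher* sub-score. The only such
  value on the printed grid is SpO₂ = 89% (between "<89" and "90–93"),
  which scores 3. The fail-safe direction is deliberate: in triage, an
  ambiguous reading should escalate, not reassure.
* **Overlaps.** Overlapping bands are a configuration error raised when a
  table is loaded; they are never silently resolved.

Other conventions: "age > 65" is a strict inequality (exactly 65 scores 0);
the consciousness row has four scored levels with confused/agitated as one
level and pain/unresponsive as one level; token parsing is
case-insensitive. Missing physiological values are an error under the
default `strict` policy — the validation study discarded incomplete forms,
so silently imputing would change the instrument. The opt-in
`missing_zero` policy scores a missing parameter as normal and logs each
affected record.

Two scoring paths (per-record dataclasses and a vectorised DataFrame path)
are kept consistent by a dedicated test.

## Diagnostic evaluation

Positivity is `score >= threshold`. The AUROC is the tie-corrected
pair-comparison probability P(S⁺ > S⁻) + ½·P(S⁺ = S⁻), computed from
per-observation placement values (O(n log n)); a brute-force O(n²) pair
count and scikit-learn serve as independent oracles in the tests. The
default 95% CI is DeLong's structural-component estimator; a stratified
percentile bootstrap is available as a cross-check and the two agree within
0.01 on a 500-patient cohort in the test suite. Youden's J selects the
optimal cutpoint, with ties broken toward the higher (more specific)
cutoff. Proportions with zero denominators are reported as NaN rather than
raising.

## Synthetic cohort generator

Labels are drawn first (`needs_ems ~ Bernoulli(0.684)`), then a latent
severity `z` (negatives standardised to N(0, 1); positives N(μ₁, σ₁) with
the shipped values μ₁ = 1.89, σ₁ = 2.30). All measurements depend on the
label only through `z`:

* each vital sign's sub-score band is chosen by a cumulative-logit link
  P(score ≥ k | z) = expit(slope·z − cₖ), and the measured value is drawn
  uniformly on the chosen band's printed grid — so the band-table engine is
  genuinely exercised, not bypassed;
* two-sided bands (brady/tachy) pick the high side with a fixed
  probability (0.8 respiratory, 0.75 heart rate, 0.7 temperature —
  tachypnea, tachycardia and fever are the common direction in medical
  emergencies);
* open-ended bands are capped at documented physiological extremes
  (respiratory rate 2–60, heart rate 20–200, SBP 40–250, temperature
  30–42 °C, SpO₂ ≥ 60) — configurable;
* social flags are Bernoulli with logistic links on `z`; performance
  status uses an ordinal link; age is a truncated normal conditional on the
  age>65 flag, clamped after rounding so flag and emitted age always agree.

The draw order is fixed (label, severity, vitals in instrument order,
social factors, age), so cohorts are bit-reproducible given
(config, n, seed), and reusing seeds across candidate configs gives common
random numbers during calibration.

A structural feature worth naming: the fitted configuration uses a
**two-tier link pattern**. Heart rate, respiratory rate and SBP have weak
("noisy") links — mild derangements common in both classes — while SpO₂,
temperature and consciousness have steep links that essentially only fire
in the severe subgroup. This is what lets the scored cohort show a modest
physiological AUROC (≈0.69, from heavy class overlap at 0–2 points)
*simultaneously* with a very high PPV at total ≥ 4 (≈0.976, because
negatives almost never accumulate four points).

## Calibration

Calibration minimises a weighted sum of squared relative deviations
between achieved and target summary values, where "achieved" always means:
simulate, score with the real engine, evaluate with the real ROC module,
average over replicates with common random numbers. The optimizer is
Nelder-Mead over a 16-component adjustment vector (prevalence on the logit
scale; severity location/spread; shared shift/scale/slope multipliers for
the physiological links; per-flag intercept and slope; performance-status
shift and slope; the two age-stratum means), with an explicit initial
simplex (scipy's default step for zero-valued coordinates is far too small
to move the shift components) and optional chained restarts. Components can
be pinned (`fixed=`): the shipped run pinned the class separation after
observing that the pairwise-ranking ceiling Φ(μ₁/√(1+σ₁²)) must exceed the
total-score AUROC target, and pinned the isolation/chronic/age-slope links
at modest, clinically sensible values rather than let the optimizer drive
them degenerate.

**An inconsistency in the published constraints.** The printed flag
marginals (age>65 32.2%, isolation 14.3%, chronic disease 52.5%) sum to
0.99, which already exceeds the printed social-score mean of 0.75 — yet the
social score equals those flags *plus* performance status. No generator of
any kind can satisfy both; the constraint set is internally contradictory.
The shipped calibration therefore sets the three marginal weights to zero
and matches the score-level summaries and operating characteristics
instead; the resulting cohort has correspondingly lower flag rates (age>65
≈ 13%, isolation ≈ 9%, chronic ≈ 15%), and its over-65 stratum skews old
(the cohort age mean and SD are matched with fewer over-65 patients).
`default_constraints()` still reports every printed value at weight 1 so
users can choose their own compromise. The operating characteristics (PPV
at ≥ 4, weight 3; the three AUROCs, weight 2) were up-weighted as the
study's primary endpoints.

The shipped `reference_config` is **one member of the family** of
generators consistent with the printed summaries, not a reconstruction of
the unpublished patient-level data; its calibration report (achieved vs
target for every constraint) ships alongside it.

## What the generator does and does not emulate

It reproduces the two-class structure, the score-level moments, the age
distribution and the printed operating characteristics. It does not model
temporal vital-sign trajectories, correlations between vitals beyond the
shared latent severity, sex (it does not enter the score, and its published cohort
breakdown is internally inconsistent), trauma/pediatric/pregnant
populations (excluded from the study), or the true flag marginals (see
above). Passing tests therefore show that the instrument, evaluation stack
and generator jointly reproduce the published summary behaviour — not that
the generator mimics real prehospital patients in any finer detail.

## Numerical choices and problem sizes

* Sample SD (n−1) throughout; displayed percentages rounded half-up to one
  decimal, means/SDs to two, matching the printed precision.
* Stochastic reproduction checks use the study's cohort size (n = 2157)
  averaged over 20 seeds, the scale at which the 20-seed mean of each
  summary is stable to well within its tolerance.
* Calibration defaults: n = 4000 per evaluation, 2 replicates; the
  parameter-recovery tests use a 300-iteration budget with 2 restarts,
  which recovers a perturbed known configuration to ≲2% per constraint
  (5% asserted).
* Bootstrap CIs default to 2000 replicates (10 000 in the DeLong
  cross-check test); fewer than 100 logs a warning.

## Known limitations

* Nelder-Mead is a local search: recovery is demonstrated for moderate
  perturbations around a working configuration, not from arbitrary starts;
  poor starting points benefit from the staged/restart strategy described
  above.
* The DeLong variance is asymptotic; with a single positive (or negative)
  the interval is wide and should not be trusted, though it is computed
  without error.
* The generator's within-band uniform sampling produces flat value
  distributions inside each band, which is adequate for score-level work
  but not for analyses of the raw vital-sign distributions themselves.
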