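# pmews

Tools for the **physiological–social modified early warning score (PMEWS)**,
a prehospital triage instrument for deciding whether a patient with a
medical (non-traumatic) complaint needs an emergency-medical-services (EMS)
response.

The package provides, for researchers and EMS analysts:

* a faithful implementation of the banded PMEWS scoring algorithm,
* diagnostic evaluation of any integer score against a gold-standard
  needs-EMS label (ROC curve, AUROC with 95% CI, cutoff operating
  characteristics, Youden-optimal cutpoint, score-by-disposal distribution),
* a latent-severity synthetic cohort generator, calibrated so that the full
  simulate → score → evaluate chain reproduces the published cohort
  summary statistics of the instrument's validation study, and
* a command-line interface (`pmews`) tying these into a study-replication
  pipeline.

## The instrument

PMEWS is the sum of two components:

* **Physiological (MEWS) component, 0–17.** Respiratory rate, SpO₂, heart
  rate, systolic blood pressure (each banded 0–3), temperature (0–2) and
  consciousness (Alert 0 / Confused–agitated 1 / Voice 2 /
  Pain–unresponsive 3). Each measured value is rounded half-up to the
  printed band precision and looked up in an interval table; values falling
  in a printed gap (e.g. SpO₂ = 89%) take the more severe adjacent band's
  score.
* **Social component, 0–7.** One point each for age > 65 (strict), social
  isolation (lives alone / no fixed abode) and chronic disease, plus the
  0–4 performance-status scale.

Total PMEWS ranges 0–24; patients with **PMEWS ≥ 4** are flagged as needing
an EMS response. The band tables ship as a versioned JSON resource
(`pmews/data/pmews_bands_v1.json`) so the instrument is auditable and
swappable.

## Worked example

Simulate a study-sized cohort from the shipped calibrated generator, score
it, and evaluate the three scores against the gold-standard label:

```bash
$ pmews run --simulate --n 2157 --seed 1 --out study/
AUROC (total): 0.726 (95% CI 0.706-0.747)
AUROC (physiological): 0.714 (95% CI 0.693-0.734)
AUROC (social): 0.651 (95% CI 0.633-0.669)
cutoff >= 4: sensitivity 0.345, specificity 0.977, PPV 0.972
artifacts -> study/
```

The AUROCs say how well each score ranks patients who truly needed EMS
above those who did not (0.5 = chance); the PPV line says that 97.2% of
patients flagged by the ≥ 4 rule in this cohort truly needed an EMS
response. `study/` then contains the scored CSV, the cohort summary
(`summary.txt`):

```
Character                              N       %
Age > 65                             289    13.4
Social isolation                     200     9.3
Chronic disease                      346    16.0
Need of the EMS response            1495    69.3
Did not require the EMS response     662    30.7

                          Mean      SD
Age                      50.93   22.50
Physiological score       2.01    2.65
Social score              0.71    1.29
PMEWS                     2.72    3.64
```

plus per-score ROC point CSVs, the integer cutoff sweep, the
score-by-disposal table and a manifest that makes the run bit-reproducible.

The same pipeline is available as a library:

```python
from pmews import RunConfig, reference_config, run_study

report = run_study(RunConfig(generator=reference_config(), n=2157, seed=1))
print(report.roc["total"].auroc)          # 0.726...
print(report.cutoff_performance.ppv)      # 0.971...
```

Scoring real data uses the same commands with a patient CSV
(`pmews score cohort.csv --out scored.csv`); the required columns are
documented in `pmews.scoring.REQUIRED_COLUMNS`.

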