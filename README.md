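# nephroref

Risk-based nephrology referral, analyzed properly under competing risks.

Most chronic kidney disease (CKD) is managed in primary care, and the
question of *who to send to a nephrologist* is increasingly answered with
a predicted risk rather than fixed lab thresholds: current guidance
suggests referral when the 5-year kidney-failure risk from the 4-variable
Kidney Failure Risk Equation (KFRE) exceeds 3–5%. Evaluating such a policy
on routine registry data is statistically delicate — in an elderly
population with eGFR < 60, death is ~30× more common than kidney
replacement therapy (KRT), so every performance measure has to treat death
as a competing event, not as censoring.

`nephroref` is a Python library for exactly this analysis:

- **Risk computation** — the 4-variable KFRE
  (risk = 1 − S0(t)^exp(lp), lp = Σ βᵢ(xᵢ − cᵢ) over age/10, male,
  eGFR/5, ln ACR), with eGFR from creatinine via the revised Lund–Malmö
  equation and albuminuria harmonized to ACR mg/g from ACR, PCR or
  dipstick tests.
- **Local recalibration** — Cox refit of coefficients and Breslow baseline
  survival on your own records (death censored, preserving the KFRE
  structure), with parameter-recovery guarantees tested on simulation.
- **Referral rules** — KDIGO 2012, configurable fixed-threshold criteria
  (YAML), and KFRE-cutoff rules, as composable predicates.
- **Competing-risk evaluation** — Aalen–Johansen cumulative incidence,
  decile calibration with a lowest-20% view, cumulative/dynamic ROC with
  Youden threshold selection, matched sensitivity/specificity comparison,
  truncated cause-specific C-index, IPCW Brier score.
- **Decision analytics** — classification tables (PPV/NPV/FP/FN),
  reclassification matrices, competing-risk net reclassification
  improvement (NRI), decision curve analysis.
- **Synthetic registry cohorts** — a seeded generator reproducing the
  statistical structure such analyses face (repeated tests per person,
  entry eGFR < 60, dominant mortality, administrative censoring), used
  throughout the tests as a world with a known truth.

The intended audience is biostatisticians and epidemiologists validating
risk-based referral policies on registry or EHR data, and anyone needing
honest competing-risk model evaluation primitives in Python.

## Worked example

Score a patient (`examples/02_kfre_risk.py`):

```text
eGFR 23.9 ml/min/1.73m2 (revised Lund-Malmo)
harmonized ACR 300 mg/g (from dipstick 2+)
2-year KRT risk:   7.4%
5-year KRT risk:  39.1%
```

A 65-year-old man with creatinine 220 µmol/L and 2+ dipstick albuminuria
has eGFR 23.9; his 5-year KFRE risk of 39% is far beyond any referral
threshold. At the population level (`examples/06_full_pipeline.py`, 3000
synthetic persons, seed 6):

```text
          model        kind  cutoff  sens  spec   ppv  referral_fraction
         non_na kfre_cutoff    0.03 0.714 0.834 0.017              0.169
         non_na kfre_cutoff    0.15 0.366 0.984 0.066              0.017
   recalibrated kfre_cutoff    0.09 0.349 0.992 0.097              0.010
     kdigo_2012  fixed_rule     NaN 0.487 0.813 0.011              0.188
swedish_example  fixed_rule     NaN 0.535 0.887 0.018              0.115
```

Read a row as: "refer at KFRE ≥ 3%" catches 71% of eventual 5-year KRT
cases while referring 17% of observations; raising the cutoff to 15%
trades sensitivity for a five-fold smaller referral volume and a higher
PPV — the fixed KDIGO rule refers more people (19%) for less sensitivity
than the matched KFRE operating point. `examples/03_recalibration.py`
shows the companion calibration story: a doubled local baseline hazard
makes the imported model under-predict in every risk decile, and the Cox
recalibration repairs it.

Each script in `examples/` is a narrative for one capability: cohort
simulation, single-patient scoring, recalibration, threshold selection by
competing-risk ROC, decision analytics, and the end-to-end pipeline.

## Reproducible pipeline runs

```python
import nephroref as nr

result = nr.run_pipeline(nr.RunConfig(
    sim=nr.SimConfig(n_persons=3000, seed=6),   # or input_dir="my_cohort/"
    out_dir="out", seed=6,
    models=("non_na", "recalibrated"),
    kfre_cutoffs=(0.03, 0.05, 0.09, 0.15),
))
```

writes observation records, per-model risks, calibration/ROC curves,
model-comparison, classification, reclassification, NRI and DCA tables as
tidy CSVs plus a JSON manifest; identical config + seed reproduces every
file byte for byte. Real data enters as four documented CSVs (persons,
lab_tests, dispensations, outcomes — see `nephroref.io`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

simulates a 6000-person registry cohort from the given seed and runs the
complete analysis — lab harmonization, observation building, scoring with
the imported and recalibrated KFRE, competing-risk evaluation, decision
analytics and two sensitivity subsets — leaving the full report bundle in
`results/pipeline_out/` and the (empty) target report at `--out`.

## Documentation

`docs/methods.md` describes the models, estimators, synthetic-data design
and numerical conventions, including what a green test on simulated data
does and does not establish. Shipped risk-equation constants and the
albuminuria conversion table are transcribed from external literature and
flagged in-code; re-verify them before clinical use.
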