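# xenotrial

Analysis toolkit for **PDX clinical trials (PCTs)** — population-level mouse
trials in which patient-derived xenograft (PDX) models, several mice per model
per arm, are treated with a targeted agent to map the spectrum of drug
response across patients.  The package was built around cetuximab-resistance
studies in head-and-neck squamous cell carcinoma, but every stage is generic:

- **Response classification** (`xenotrial.trial`): caliper volumes
  (TV = ½·w²·l), percent change vs. day-0 baseline, per-round
  mCR/mPR/mSD/mPD categories, and a two-round decision tree that labels each
  case *sensitive*, *intrinsic resistance*, *acquired resistance*, *DTP*
  (reversible drug-tolerant persister), *individual differences*, or
  *unevaluable*, plus cohort summaries with capped waterfall values.
- **Clonal dynamics** (`xenotrial.clonal`): cancer-cell-fraction (CCF)
  estimation from VAF, purity, copy number and multiplicity; subclone
  inference by a binomial-mixture EM with BIC model selection; three-way
  subclone fate calls (newly generated / eliminated / persistent with
  increasing, decreasing or stable subtypes); cross-case gained/lost-mutation
  tallies; hypergeometric gene-set over-representation with BH correction.
- **Repeated trajectories** (`xenotrial.trajectories`): ordered driver
  transitions (GL → e₁ → … → e_k) extracted from clone trees, recurrence
  counting across cases, and a six-class taxonomy of pre- vs post-treatment
  trajectory change.
- **Biomarker screening** (`xenotrial.biomarkers`): ROC AUC (Mann–Whitney
  rank statistic with midrank ties) between resistance groups with an
  AUC > 0.80 predictive flag, group alteration frequencies with Fisher exact
  tests, and monotone expression-trend calls over serial timepoints.
- **Synergy** (`xenotrial.synergy`): four-parameter Hill fits with censored
  IC50s, and Loewe-additivity combination indices CI = d₁/D₁ + d₂/D₂ over
  9×9 dose matrices (CI < 0.75 synergistic, CI > 1.5 antagonistic).
- **Synthetic cohorts** (`xenotrial.simdata`): a generator for clone
  populations under logistic growth with drug kill and persister switching,
  producing volume series, variant tables, expression matrices and dose
  matrices with known ground truth, so the full pipeline is testable without
  any sequencing data.

## Worked example

Simulate a small cohort and run the two-round classifier:

```bash
xenotrial simulate --n-cases 8 --seed 7 --measurement-cv 0.02 --out demo/sim
xenotrial classify --volumes demo/sim/volumes.csv --out demo/cls
```

`demo/cls/cases.tsv` then contains one row per case, e.g.

```
case_id     round1_pct  round1_cat  relapse_day  round2_pct  round2_cat  outcome
CASE_000    197.55      mPD                                              intrinsic_resistance
CASE_003    -73.70      mPR         35.0         -74.65      mPR         dtp
```

CASE_000 grew +197.6% by day 21 (mPD → intrinsic resistance).  CASE_003
regressed −73.7% (mPR), relapsed at day 35, and responded again on
re-treatment (−74.7%, mPR), the signature of a reversible drug-tolerant
persister.  `summary.json` holds the cohort counts, half-up two-decimal
percentages, and waterfall values clamped to [−100%, +200%].

The same workflow is available as library calls
(`simdata.simulate_cohort`, `trial.classify_case`, `trial.cohort_summary`),
and further stages run on the simulated variant tables and dose matrices
(`xenotrial clonal`, `xenotrial synergy`, `xenotrial run`).

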