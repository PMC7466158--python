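# ddiscreen

Signal screening for **drug–drug interactions (DDI)** in spontaneous-reporting-system
(SRS) data, built around subset reporting-odds-ratio (ROR) analysis with a
both-directions detection criterion, the Ω shrinkage measure, and a
classification-evaluation harness.

## What it does

Starting from JADER-style report tables (`DEMO.csv`, `DRUG.csv`, `REAC.csv`),
the package:

1. assembles case-level records (suspect drugs + adverse-event preferred terms),
2. enumerates (drug1, drug2, event) triples and builds the 4×2 contingency
   table `n111 … n000` for each,
3. runs detectors over the tables:
   - **subset ROR** — the ROR of drug 2 within drug-1 users and vice versa,
     with either the *previous* criterion (signal in **either** directional
     subset) or the *new* criterion (signal required in **both**),
   - **Ω shrinkage measure** (signal when Ω₀₂₅ > 0),
   - three component interaction models (additive risk difference,
     multiplicative ratio of risk ratios, Yates-corrected one-sided
     chi-square) whose intersection serves as a surrogate truth set,
4. scores signal sets against truth (accuracy, precision/PPV,
   recall/sensitivity, specificity, Youden's index, F-measure, NPV) and
   measures inter-algorithm agreement (Cohen's κ with asymptotic CI,
   positive/negative proportionate agreement), with optional stratification
   by the number of co-exposed event reports (`n111 ≥ k`),
5. generates synthetic JADER-shaped datasets with known per-pair interaction
   structure, so the full pipeline is testable without the real database.

## CLI

```bash
# generate a synthetic dataset from a YAML scenario
ddiscreen simulate --config scenario.yaml --out data/ --seed 42

# build 4x2 contingency tables for every pair co-reported with the event
ddiscreen tabulate --demo data/DEMO.csv --drug data/DRUG.csv \
    --reac data/REAC.csv --event "Stevens-Johnson syndrome" --out tables.csv

# run a detector (subset-previous, subset-new, omega, additive,
# multiplicative, chi-square, truth)
ddiscreen detect --tables tables.csv --algorithm subset-new --out new.csv
ddiscreen detect --tables tables.csv --algorithm truth --out truth.csv

# score signal sets and cross-compare them
ddiscreen evaluate --truth truth.csv --pred prev.csv --pred new.csv \
    --out-metrics metrics.csv --out-agreement agreement.csv

# one-shot synthetic recovery experiment over all detectors
ddiscreen compare --config scenario.yaml --out results/ --seed 42
```

A scenario YAML mirrors `ddiscreen.synth.ScenarioConfig`:

```yaml
n_cases: 50000
target_event: "Stevens-Johnson syndrome"
baseline_event_prob: 0.01
drugs:
  - {name: drug_a, exposure_prob: 0.05}
  - {name: drug_b, exposure_prob: 0.05}
interaction_pairs:
  - {drug1: drug_a, drug2: drug_b, f10: 0.05, f01: 0.05, f11: 0.30}
seed: 7
```

Column names default to the JADER csv headers and can be remapped with the
`--col-*` options of `tabulate` (or `ColumnMap` in the API).

## Layout

```
src/ddiscreen/
  contingency.py   case assembly, triple enumeration, 4x2 tables, csv I/O
  signals.py       ROR, subset criteria, Omega shrinkage, component models
  evaluation.py    confusion counts, metrics, kappa/agreement, stratification
  synth.py         scenario config, report generator, recovery experiments
  reference.py     published benchmark counts for the full-database screen
  cli.py           click command group (simulate/tabulate/detect/evaluate/compare)
tests/             unit, property (hypothesis) and acceptance suites
scripts/acceptance.py
```
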