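# dietmet

Diet → metabolome → glucose-metabolism analysis for cohort studies:
dietary-pattern scoring, NMR metabolite preprocessing, covariate-adjusted
association screening with FDR control, Sobel–Goodman mediation with a
cross-diet consistency filter, and longitudinal relative-risk estimation —
plus a synthetic-cohort generator that plants known mediation structure so
every stage is testable without access to restricted cohort data.

## Who this is for

Nutritional-epidemiology and metabolomics groups asking whether circulating
metabolites *mediate* the association between habitual dietary patterns and
glucose metabolism status (GMS: normal glucose metabolism / prediabetes /
type 2 diabetes). The package implements the full analysis chain as a tested
library with a thin CLI, so the design can be rerun, stress-tested on
simulated cohorts, and adapted to new data.

## What it computes

**Diet indices.** Three adherence scores per participant from food-component
intakes:

* MED (0–9): nine components scored 0/1 against sex-specific cohort medians
  (meat and dairy inverted; alcohol scores 1 inside 10–50 g/day for men,
  5–25 g/day for women);
* DASH (8–40): eight components ranked 1–5 by sex-specific quintiles, with
  unhealthy components reverse-scored (6 − rank);
* DHD-2015 (0–140): per-component 0–10 by linear interpolation between a
  threshold (score 0) and a guideline cut-off (score 10), 14 scored
  components.

**Cohort handling.** WHO-style FPG/medication GMS classification
(score 2 if FPG ≥ 7.0 mmol/L or hypoglycaemic medication; 1 if
6.1 ≤ FPG < 7.0; 0 below 6.1), a five-rule exclusion cascade with
first-match attribution and a full audit, and the covariate imputation used
for adjusted models (categoricals → explicit "unknown" level; physical
activity → sex-specific mean).

**Metabolite preprocessing.** Staged and order-enforced: QC exclusion
(including ratios that depend on dropped measures), missForest-style
iterative tree-ensemble imputation of absolute measures, half-minimum zero
replacement, ratio recomputation from the completed matrix, and
ln(x + P10) normalisation scaled to SD units.

**Screens and mediation.** Proportional-odds models for the 3-level GMS
score, binary logits for its pairs, OLS for continuous traits and
metabolites, tertile trend tests, interaction tests, Benjamini–Hochberg FDR
per screen; then, for each (diet, measure, outcome) triple, the
Sobel–Goodman test

    indirect = a·b,  se = sqrt(b²·se_a² + a²·se_b²),
    proportion mediated = a·b / c_total,

with the exact OLS identity c_total = c_direct + a·b, and a consistency
filter that keeps only measures significant with a same-signed indirect
effect in **every** diet × GMS-pair cell.

**Longitudinal.** Incidence summaries by baseline GMS and Poisson
regression RRs per SD of a measure with a log person-years offset and
robust errors.

## Worked example

```python
import dietmet as dm

sim = dm.SimConfig(
    n_raw=1000, seed=3, use_registry=False, n_mediators=3, n_null=9,
    a_diet_metab=0.6, b_metab_gms=-0.6, c_direct=-0.3,
    exclusion_counts=(5, 5, 5, 5, 5), newly_diagnosed_count=30,
    incidence_rr=0.6, rr_measure="mediator_01",
)
bundle = dm.run_pipeline(dm.RunConfig(sim=sim, seed=3), write=False)
print(bundle.manifest["n_cohort"], bundle.candidates, bundle.signature)
```

prints

```
975 ['mediator_01', 'mediator_02', 'mediator_03'] ['mediator_01', 'mediator_02', 'mediator_03']
```

The generator planted three mediators carrying a = 0.6 SD of metabolite per
SD of diet score and b = −0.6 on the GMS liability; the screens flag all
three as FDR-significant for every diet and for GMS, and the consistency
filter retains them as the stable signature. The adjusted
proportional-odds model shows the planted protective diet effect (MED
tertile 3 vs 1: OR 0.02, 95% CI 0.01–0.03 — strong by construction), a
typical mediation cell reports indirect −0.020 with proportion mediated
0.16 (q = 1.5 × 10⁻⁷), and the follow-up stage recovers the planted
relative risk of incident type 2 diabetes per SD of `mediator_01` in the
prediabetes stratum:

```
stratum            measure      rr     95% CI        events
prediabetes->T2D   mediator_01  0.58   (0.43, 0.77)  27
```

against a planted RR of 0.6.

With `use_registry=True` (the default) the generator instead emits a full
231-measure targeted-NMR-style panel (98 lipoprotein-subclass measures,
52 lipids/fatty-acids/low-molecular-weight metabolites of which 5 are
QC-flagged, 81 ratios), which preprocessing reduces to the 226-measure
analysis panel.

## Command line

```bash
dietmet simulate --seed 1 --n-raw 3807 --out data/
dietmet score --participants data/participants.tsv --out scores.tsv
dietmet prep --metabolites data/metabolites.tsv --out normalized.tsv
dietmet run-all --config run.yaml --seed 1 --out results/
dietmet sensitivity --config run.yaml --seed 1 --out results_sens/
```

## Layout

```
src/dietmet/
  synth.py         synthetic cohorts with planted mediation + follow-up
  cohort.py        GMS classification, exclusion cascade, covariate imputation
  dietscores.py    MED / DASH / DHD engines, tertiles, DietScorer transformer
  metabprep.py     staged metabolite preprocessing, MetabolitePreprocessor
  assoc.py         ordinal/logit/linear screens, trend, interaction, BH-FDR
  mediation.py     Sobel-Goodman tests, screen, consistency filter
  longitudinal.py  incidence summaries, Poisson relative risks
  pipeline.py      end-to-end orchestration + sensitivity rerun
  cli.py           command-line interface
  data/            default measure registry and DHD component table (TSV)
```

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
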