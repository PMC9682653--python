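# Methods

## The analysis model

The pipeline treats glucose metabolism status (GMS) as a three-level
ordinal outcome — 0 normal glucose metabolism (NGM), 1 prediabetes,
2 type 2 diabetes — defined operationally from fasting plasma glucose
(FPG) and medication: score 2 if FPG ≥ 7.0 mmol/L or any hypoglycaemic
medication, 1 if 6.1 ≤ FPG < 7.0 without medication, 0 if FPG < 6.1
without medication. FPG values in the open interval (6.9, 7.0) are scored
as prediabetes so the rule partitions the real line at the 7.0 cut; 2-h
OGTT criteria are not used (participants without an OGTT are classified
from FPG and medication alone, with a finger-prick FPG as fallback).

Exposure is adherence to a dietary pattern, summarised by three indices
(MED 0–9, DASH 8–40, DHD-2015 0–140) computed from food-component intakes
against cohort-derived, sex-specific reference statistics. Candidate
mediators are 226 normalized NMR metabolite measures (145 absolute
concentrations + 81 ratios). The causal question — does the diet–GMS
association run through specific metabolites? — is addressed by the
classical three-regression Sobel–Goodman procedure on complete-case rows:

1. mediator ~ exposure + covariates → a, se_a
2. outcome ~ exposure + mediator + covariates → b, se_b and the direct
   effect c′
3. outcome ~ exposure + covariates → total effect c

with indirect effect a·b, Sobel SE √(b²se_a² + a²se_b²), Goodman variants
adding/subtracting se_a²se_b² under the root, a two-sided normal p, and
proportion mediated a·b/c. All three stages are least squares, including
for the ordinal score and the binary pair indicators — this reproduces the
behaviour of the classical procedure, keeps the decomposition
c = c′ + a·b exact (the rows are fixed across stages), and makes the
proportion mediated well-defined; a logistic-stage variant would break the
exact decomposition and is deliberately not the default. The proportion is
reported signed and untruncated; values outside [0, 1] are flagged as
inconsistent mediation rather than clipped.

A measure belongs to the **stable signature** when its mediation is
FDR-significant with a same-signed indirect effect in every diet ×
GMS-pair cell (3 diets × 3 pairs = 9 cells). Measures with incomplete cell
coverage are excluded — the filter is strict by design: it asks for a
signal robust to both the choice of diet index and the glycaemic contrast.

## Diet indices

* **MED**: healthy components (vegetables, legumes, fruits+nuts, fish,
  cereals, (MUFA+PUFA)/SFA) score 1 at or above the sex-specific cohort
  median; meat and dairy score 1 strictly below it; alcohol scores 1 in
  10–50 g/day (men) / 5–25 g/day (women), inclusive at both ends.
* **DASH**: sex-specific quintile boundaries at the empirical 20/40/60/80
  percentiles; healthy components score their quintile rank 1–5, unhealthy
  components (red/processed meat, sugar-sweetened beverages, sodium) score
  6 − rank. The non-standard orientation (raw rank for unhealthy
  components) exists behind a flag for sensitivity use; the adherence
  convention with reversal is the default because it is the only reading
  consistent with the index's 8–40 "higher = healthier" range.
* **DHD-2015**: each scored component maps linearly from a threshold
  (score 0) to a guideline cut-off (score 10), clamped; healthy components
  saturate at/above the cut-off, unhealthy at/below it. The packaged table
  scores 14 components (maximum 140); coffee is carried unscored, because
  a food-frequency instrument typically cannot separate filtered from
  unfiltered coffee, and 14 × 10 matches the index's printed maximum. The
  threshold/cut-off values are packaged defaults emulating the 2015 Dutch
  guideline operationalisation and are user-replaceable via TSV.

Quantile convention everywhere (medians, quintiles, tertiles, the P10
shift): empirical quantiles with linear interpolation; values tied with a
boundary fall into the lower band. Tertiles are cut at the 1/3 and 2/3
quantiles of the analysis cohort, label 1 = low adherence. Reference
medians/quintiles are computed on the analysis cohort (post-exclusion).

## Metabolite preprocessing

Stages are order-enforced (raw → qc → imputed → zero-replaced →
ratios-recomputed → normalized); calling a stage out of order raises.

* **QC**: named failures (glutamine, pyruvate, glycerol,
  β-hydroxybutyrate, acetate on the default panel) and any
  registry-flagged measure are dropped, together with every ratio whose
  definition references a dropped measure.
* **Imputation** (absolute measures only): chained iterative regression
  with an ExtraTrees learner (10 trees, depth 8 by default), at most 10
  rounds with an early tolerance stop, seeded and deterministic. Ratios
  are not imputed — they are recomputed later from the completed matrix.
  Imputation pools both measurement batch-years; batch-year is carried as
  a model covariate instead.
* **Zeros**: exact zeros become half the smallest strictly positive
  observed value of that measure; an all-zero measure is an error.
* **Ratios**: every ratio column is overwritten by its registry definition
  (numerator/denominator sums of absolute measures, ×100 for %-unit
  ratios).
* **Normalisation**: y = ln(x + P10(x)) per measure, then scaled to SD
  units (mean 0, SD 1, ddof = 1). The P10 shift is computed after zero
  replacement (normalisation is the final step). Normalisation is
  rank-preserving per measure.

## Association screens

Proportional-odds (ordinal logistic) regression for the 3-level GMS score,
binary logit for the pairs 0v1/0v2/1v2, OLS for continuous outcomes
(standardized betas; optional sex and obesity strata, BMI ≥ 30 vs < 30).
Crude and adjusted variants differ only by the adjustment set (age, sex,
BMI, education, income, smoking, energy intake, daily glucose intake,
eGFR, physical activity, CVD history, lipid-modifying medication,
metabolomics batch-year); "unknown" indicator levels are kept as their own
category. Continuous covariates are z-scored inside the likelihood-based
fits — a pure reparameterisation that leaves the exposure estimates
unchanged but conditions the optimisation. Wald CIs throughout; the
proportional-odds assumption is not formally tested. The trend test refits
the model replacing tertile dummies with each participant's tertile-median
score as one continuous covariate; interaction tests add exposure ×
modifier product terms to the adjusted ordinal model and report the joint
Wald p. The interaction is parameterised as diet × modifier (the natural
reading for an exposure-modifier question on a GMS outcome).

FDR control is Benjamini–Hochberg step-up, one family per screen: each
diet's metabolite screen (226 tests) and the GMS ordinal screen (226
tests) are separate families; the mediation screen is corrected over all
of its cells. Signature candidates are the intersection of the three
per-diet FDR-significant sets with the GMS-significant set, in registry
order.

## Longitudinal stage

Follow-up is a long table (id, baseline GMS, year, cumulative incident
flag), up to 7 years. Baseline type 2 diabetes is excluded from the risk
set. The RR per SD of a measure is Poisson log-linear regression of the
ever-incident indicator with a log person-years offset (years to first
event or censoring) and HC0 robust errors; a no-offset mode matches a
plain per-person rate reading of RR and equals the offset fit up to an
intercept shift when exposure time is constant. Measures enter in SD units
of the normalized matrix.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
the study's own scale by default (n_raw = 3807; exclusion counts
48/43/168/69/38 leaving 3441; NGM/prediabetes/T2D ≈ 57/15/28%; 135 newly
diagnosed T2D at baseline; follow-up duration ≈ N(5.83, 0.91) years capped
at 7; per-year baseline incidence 0.0017 (NGM) and 0.024 (prediabetes),
giving ≈1% and ≈13% cumulative incidence):

* a latent healthiness factor h ~ N(0,1) shifts log-normal component
  intakes up (healthy) or down (unhealthy), making all three diet indices
  positively correlated, as FFQ-derived indices are in practice;
* the planted exposure Z is the standardized MED score **computed from the
  generated intakes** — so the downstream three-regression fit on the
  actually scored index is the exact generating exposure, not a proxy;
* planted mediators satisfy M_j = a_j·Z + noise (unit variance) on the
  z-scale; absolute measures are log-normal with the mediator signal
  injected on the log scale; ratios follow their registry definitions;
* the ordinal liability is L = Σ b_j·M_j + c′·Z + covariate terms + N(0,1),
  thresholded at two cut-points; with the default `gms_thresholds=None`
  the cut-points sit at the empirical liability quantiles matching the
  57/15/28% class mix. FPG and medication flags are then drawn
  consistently with the class, so the classifier reproduces the planted
  GMS exactly;
* the per-mediator planted proportion mediated is
  a_j·b_j / (c′ + Σ_k a_k·b_k);
* exclusion conditions are planted on disjoint record sets as the actual
  data condition each rule tests (all-missing metabolites, missing
  glycaemic inputs, implausible kcal, a blanked diet component, a
  non-Caucasian marker), making the cascade arithmetic exactly checkable;
* follow-up events arise from a per-year hazard base·RR^z, monotone
  (once incident, always incident).

Default planted effects are a = 0.35, b = −0.25, c′ = −0.3 per SD — a
protective-diet configuration of realistic epidemiological magnitude that
the screens can recover at the default cohort size. Everything is
deterministic given (config, seed).

What the generator does **not** emulate: the true inter-metabolite
correlation of a targeted NMR panel (only an optional single shared factor
via `low_rank_corr`), measurement error in the FFQ, informative
missingness, or time-varying diet. Passing recovery tests therefore shows
the estimators are correct under the assumed data-generating model, not
that real-data effect estimates would be unbiased.

## Numerical choices

* Quantiles: linear interpolation; ties to the lower band, everywhere.
* Normalized columns must achieve |mean| < 1e-8 and SD 1 (ddof = 1).
* The Sobel decomposition identity is asserted to 1e-8 on every fit.
* Goodman-2 SEs with a negative radicand, and proportions with c_total = 0,
  are reported as undefined with a flag instead of raising.
* Ordinal fits use BFGS (500 iterations); non-convergence raises a
  FitError carrying the optimizer diagnostics, and screens log the error
  and continue past single cells.
* Degenerate inputs error early and by name: tertile assignment with < 3
  distinct values, reference cut-offs from a sex stratum of < 5, an
  all-zero or all-missing measure, a constant interaction modifier.

## Problem sizes used in the tests

Unit and acceptance tests run the generator at the sizes each check needs:
study scale (n_raw = 3807) for the cascade and class-mix checks; n = 5000
for mediation-proportion and relative-risk recovery; 20 replicates of a
reduced null configuration (n = 500, 16 measures, age/sex/BMI adjustment)
for the false-discovery calibration of the full pipeline; and n ≈ 400–1000
planted-cohort runs for the end-to-end and determinism checks. These sizes
are the package's own trade-off between Monte-Carlo precision and a test
suite that stays fast enough to run on every change.

## Known limitations

* Mediation is associational: no counterfactual identification, no
  exposure–mediator interaction, no multiple-mediator joint model, no
  sensitivity analysis for unmeasured confounding.
* The ordinal outcome enters the mediation stages numerically (0/1/2 or a
  pair indicator); effect sizes on that scale are not odds ratios.
* HOMA-IR is consumed as a provided column; it is not computed from
  insulin and glucose.
* The packaged measure registry reproduces the *structure* of a targeted
  NMR panel (names, clusters, ratio definitions, QC flags), not its
  measured values or correlations; it is a synthetic emulation and is
  user-replaceable.
* The DHD component table's threshold/cut-off defaults are an
  operationalisation choice; users with the official supplementary table
  should supply it via `DhdComponentTable.from_tsv`.
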