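"""Cohort ingestion: GMS classification, exclusion cascade, covariate imputation.

Glucose metabolism status (GMS) is the three-level ordinal state used
throughout: 0 = normal glucose metabolism (NGM, fasting plasma glucose
< 6.1 mmol/L and no hypoglycaemic medication), 1 = prediabetes (FPG
6.1–6.9 mmol/L, no medication), 2 = type 2 diabetes (FPG ≥ 7.0 mmol/L or
hypoglycaemic medication).  Participants who skipped the OGTT (insulin users
or finger-prick FPG > 11 mmol/L) are classified from their FPG value and
medication information alone.  FPG values in the open interval (6.9, 7.0)
are classified as prediabetes so the rule partitions the real line at 7.0.

The exclusion cascade evaluates five rules in a fixed order, attributing
each excluded record to the first rule it fails:

1. no measured metabolites;
2. GMS not classifiable (all glycaemic inputs missing);
3. implausible energy intake (< 800 or > 4200 kcal/day for men,
   < 500 or > 3500 kcal/day for women — boundaries kept);
4. incomplete diet-component data;
5. non-Caucasian ethnicity marker.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dietscores import REFERENCE_COMPONENTS

NGM, PREDIABETES, T2D = 0, 1, 2

EXCLUSION_RULES = [
    "no_metabolites",
    "no_gms",
    "implausible_energy",
    "incomplete_diet",
    "non_caucasian",
]

#: categorical adjustment covariates that take an explicit "unknown" level
CATEGORICAL_COVARIATES = ["education", "income", "smoking", "cvd_history"]

#: diet columns a record must carry completely to pass exclusion rule 4
DIET_COMPONENT_COLUMNS = sorted(
    set(REFERENCE_COMPONENTS)
    | {"alcohol", "vegetables", "fruits", "wholegrain", "legumes", "nuts",
       "fish", "tea", "dairy", "fats_oils", "red_meat", "processed_meat",
       "sweet_beverages", "salt", "coffee"}
)


def classify_gms(
    fpg: float | None,
    on_hypoglycemic_meds: bool = False,
    uses_insulin: bool = False,
    fingerprick_fpg: float | None = None,
) -> int | None:
    """GMS score 0/1/2 from fasting plasma glucose and medication flags.

    Returns ``None`` (classification-missing signal) when every glycaemic
    input is absent — such records are exclusion-rule-2 candidates.
    Medication dominates: any hypoglycaemic-medication user is scored 2
    regardless of FPG.  Insulin users without a venous FPG fall back to the
    finger-prick value.
    """
    if on_hypoglycemic_meds:
        return T2D
    value = fpg
    if value is None or (isinstance(value, float) and np.isnan(value)):
        value = fingerprick_fpg
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if value >= 7.0:
        return T2D
    if value >= 6.1:
        return PREDIABETES
    return NGM


def classify_gms_frame(df: pd.DataFrame) -> pd.Series:
    """Vectorised GMS classification; NaN where unclassifiable."""
    fpg = df["fpg"].to_numpy(dtype=float)
    meds = df["on_hypoglycemic_meds"].fillna(False).to_numpy(dtype=bool)
    finger = (
        df["fingerprick_fpg"].to_numpy(dtype=float)
        if "fingerprick_fpg" in df.columns
        else np.full(len(df), np.nan)
    )
    value = np.where(np.isnan(fpg), finger, fpg)
    out = np.full(len(df), np.nan)
    out[meds] = T2D
    known = ~meds & ~np.isnan(value)
    out[known & (value >= 7.0)] = T2D
    out[known & (value >= 6.1) & (value < 7.0)] = PREDIABETES
    out[known & (value < 6.1)] = NGM
    return pd.Series(out, index=df.index)


def is_plausible_energy(sex: str, kcal: float) -> bool:
    """Energy-intake plausibility (exclusion is strict: <800/>4200 men,
    <500/>3500 women; boundary values are kept)."""
    if sex == "male":
        return 800.0 <= kcal <= 4200.0
    if sex == "female":
        return 500.0 <= kcal <= 3500.0
    raise ValueError(f"unknown sex {sex!r}")


@dataclass
class ExclusionAudit:
    """Per-rule exclusion tallies plus each record's first failing rule."""

    counts: dict = field(default_factory=dict)
    n_input: int = 0
    n_survivors: int = 0
    first_failing_rule: pd.Series = field(default=None, repr=False)

    def __post_init__(self):
        total_excluded = sum(self.counts.values())
        if self.n_input - total_excluded != self.n_survivors:
            raise ValueError("audit arithmetic does not balance")

    def to_json(self, path=None) -> str:
        payload = {
            "n_input": self.n_input,
            "counts": self.counts,
            "n_survivors": self.n_survivors,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _rule_failures(df: pd.DataFrame,
                   metabolites: pd.DataFrame | None) -> dict[str, pd.Series]:
    """Boolean failure mask per rule, evaluated on the actual data condition."""
    n = len(df)
    if metabolites is not None:
        no_metab = metabolites.reindex(df.index).isna().all(axis=1)
    elif "metabolites_measured" in df.columns:
        no_metab = ~df["metabolites_measured"].fillna(False).astype(bool)
    else:
        no_metab = pd.Series(False, index=df.index)

    no_gms = classify_gms_frame(df).isna()

    male = df["sex"] == "male"
    kcal = df["energy_intake"].to_numpy(dtype=float)
    implausible = pd.Series(
        np.where(male, (kcal < 800) | (kcal > 4200),
                 (kcal < 500) | (kcal > 3500)),
        index=df.index,
    )
    implausible |= pd.Series(np.isnan(kcal), index=df.index)

    diet_cols = [c for c in DIET_COMPONENT_COLUMNS if c in df.columns]
    incomplete = (
        df[diet_cols].isna().any(axis=1)
        if diet_cols
        else pd.Series(False, index=df.index)
    )

    non_cauc = df.get(
        "ethnicity", pd.Series("caucasian", index=df.index)
    ).ne("caucasian")

    assert len(no_metab) == n
    return {
        "no_metabolites": no_metab,
        "no_gms": no_gms,
        "implausible_energy": implausible,
        "incomplete_diet": incomplete,
        "non_caucasian": non_cauc,
    }


def apply_exclusion_cascade(
    records: pd.DataFrame,
    metabolites: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, ExclusionAudit]:
    """Apply the five exclusion rules in order; first-match attribution.

    Returns the surviving cohort and an :class:`ExclusionAudit` whose
    per-rule counts sum with the survivor count to the input count.
    Idempotent: re-running on the survivors excludes no one.
    """
    failures = _rule_failures(records, metabolites)
    first = pd.Series("", index=records.index, dtype=object)
    excluded = pd.Series(False, index=records.index)
    counts = {}
    for rule in EXCLUSION_RULES:
        hit = failures[rule] & ~excluded
        counts[rule] = int(hit.sum())
        first[hit] = rule
        excluded |= hit
    survivors = records.loc[~excluded]
    audit = ExclusionAudit(
        counts=counts,
        n_input=len(records),
        n_survivors=len(survivors),
        first_failing_rule=first[excluded],
    )
    return survivors, audit


def impute_covariates(cohort: pd.DataFrame) -> pd.DataFrame:
    """Covariate imputation as used for the adjusted models.

    Missing categorical covariates become the explicit level ``"unknown"``
    (carried as its own category in design matrices); missing physical
    activity becomes the sex-specific mean of the non-missing values.
    """
    out = cohort.copy()
    for col in CATEGORICAL_COVARIATES:
        if col in out.columns:
            out[col] = out[col].astype(object).where(out[col].notna(),
                                                     "unknown")
    if "physical_activity" in out.columns:
        for s, idx in out.groupby("sex").groups.items():
            vals = out.loc[idx, "physical_activity"]
            if vals.isna().all():
                raise ValueError(
                    f"sex stratum {s!r} has no observed physical activity"
                )
            out.loc[idx, "physical_activity"] = vals.fillna(vals.mean())
    return out
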