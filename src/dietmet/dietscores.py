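"""Dietary-pattern adherence scores: MED, DASH and DHD-2015.

Three index engines over per-participant food-component intakes:

* **MED** (0–9): nine components scored 0/1 against sex-specific cohort
  medians; meat and dairy inverted; alcohol scored 1 inside a sex-specific
  moderate band (10–50 g/day men, 5–25 g/day women, inclusive).
* **DASH** (8–40): eight components ranked 1–5 by sex-specific cohort
  quintiles; unhealthy components (red/processed meat, sugar-sweetened
  beverages, sodium) reverse-scored (6 − rank) under the standard adherence
  convention.
* **DHD-2015** (0–140): per-component 0–10 scores by linear interpolation
  between a threshold (score 0) and a guideline cut-off (score 10); 14 scored
  components (coffee is carried in the packaged table but unscored).

Quantile convention repo-wide: empirical quantiles with linear interpolation
(`numpy.quantile` default); values tied with a boundary fall in the lower
band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

MED_HEALTHY = ["vegetables", "legumes", "fruits_nuts", "fish", "cereals",
               "mufa_pufa_sfa"]
MED_UNHEALTHY = ["meat", "dairy"]
MED_ALCOHOL_BAND = {"male": (10.0, 50.0), "female": (5.0, 25.0)}

DASH_HEALTHY = ["vegetables", "fruits", "nuts_legumes", "wholegrain",
                "low_fat_dairy"]
DASH_UNHEALTHY = ["red_processed_meat", "sugar_beverages", "sodium"]

#: every column a cutoff table must cover
REFERENCE_COMPONENTS = sorted(set(MED_HEALTHY + MED_UNHEALTHY
                                  + DASH_HEALTHY + DASH_UNHEALTHY))


class MissingComponentError(KeyError):
    """A required intake component is absent."""


@dataclass
class ReferenceCutoffs:
    """Sex-specific medians (MED) and quintile boundaries Q1–Q4 (DASH).

    ``medians``:  {sex: {component: median}};
    ``quintiles``: {sex: {component: ndarray of the 20/40/60/80 percentiles}}.
    """

    medians: dict = field(default_factory=dict)
    quintiles: dict = field(default_factory=dict)


def compute_reference_cutoffs(
    intakes: pd.DataFrame,
    sex: pd.Series | str = "sex",
    components: list[str] | None = None,
    min_stratum: int = 5,
) -> ReferenceCutoffs:
    """Sex-stratified medians and quintile boundaries from cohort intakes.

    Boundaries are the empirical 20/40/60/80 percentiles (linear
    interpolation) of non-missing intakes within each sex stratum.
    """
    if isinstance(sex, str):
        sex = intakes[sex]
    if components is None:
        components = [c for c in REFERENCE_COMPONENTS if c in intakes.columns]
    cut = ReferenceCutoffs()
    for s, idx in sex.groupby(sex).groups.items():
        sub = intakes.loc[idx, components]
        n = len(sub)
        if n < min_stratum:
            raise ValueError(
                f"sex stratum {s!r} has only {n} participants "
                f"(minimum {min_stratum} for quintile cut-offs)"
            )
        med, quint = {}, {}
        for comp in components:
            vals = sub[comp].dropna().to_numpy(dtype=float)
            if len(vals) < min_stratum:
                raise ValueError(
                    f"component {comp!r} has only {len(vals)} non-missing "
                    f"values in sex stratum {s!r}"
                )
            med[comp] = float(np.median(vals))
            quint[comp] = np.quantile(vals, [0.2, 0.4, 0.6, 0.8])
        cut.medians[s] = med
        cut.quintiles[s] = quint
    return cut


# ---------------------------------------------------------------------------
# MED
# ---------------------------------------------------------------------------

def med_score(
    intakes: Mapping[str, float],
    cutoffs: ReferenceCutoffs,
    sex: str,
    alcohol_g: float,
) -> int:
    """Nine-component Mediterranean-diet adherence score (0–9).

    Healthy components score 1 at or above the sex median, meat and dairy
    score 1 strictly below it, alcohol scores 1 inside the sex band
    (inclusive at both ends).
    """
    med = cutoffs.medians[sex]
    total = 0
    for comp in MED_HEALTHY:
        if comp not in intakes or pd.isna(intakes[comp]):
            raise MissingComponentError(f"MED component {comp!r} missing")
        total += int(intakes[comp] >= med[comp])
    for comp in MED_UNHEALTHY:
        if comp not in intakes or pd.isna(intakes[comp]):
            raise MissingComponentError(f"MED component {comp!r} missing")
        total += int(intakes[comp] < med[comp])
    lo, hi = MED_ALCOHOL_BAND[sex]
    total += int(lo <= alcohol_g <= hi)
    return total


def med_scores(intakes: pd.DataFrame, cutoffs: ReferenceCutoffs,
               sex: pd.Series) -> pd.Series:
    """Vectorised :func:`med_score` over a cohort table with an ``alcohol`` column."""
    out = pd.Series(0, index=intakes.index, dtype=int)
    for s in sex.unique():
        mask = (sex == s).to_numpy()
        med = cutoffs.medians[s]
        sub = intakes.loc[mask]
        score = np.zeros(mask.sum(), dtype=int)
        for comp in MED_HEALTHY:
            score += (sub[comp].to_numpy(dtype=float) >= med[comp]).astype(int)
        for comp in MED_UNHEALTHY:
            score += (sub[comp].to_numpy(dtype=float) < med[comp]).astype(int)
        lo, hi = MED_ALCOHOL_BAND[s]
        alc = sub["alcohol"].to_numpy(dtype=float)
        score += ((alc >= lo) & (alc <= hi)).astype(int)
        out.loc[mask] = score
    return out


# ---------------------------------------------------------------------------
# DASH
# ---------------------------------------------------------------------------

def _quintile_rank(values: np.ndarray, boundaries: np.ndarray) -> np.ndarray:
    """Rank 1–5; a value equal to a boundary falls in the lower band."""
    return 1 + (values[:, None] > boundaries[None, :]).sum(axis=1)


def dash_score(
    intakes: Mapping[str, float],
    cutoffs: ReferenceCutoffs,
    sex: str,
    reverse_unhealthy: bool = True,
) -> int:
    """Eight-component DASH adherence score (8–40) from sex-specific quintiles.

    ``reverse_unhealthy=False`` scores unhealthy components by raw quintile
    rank (the non-standard orientation), for sensitivity use only.
    """
    quint = cutoffs.quintiles[sex]
    total = 0
    for comp in DASH_HEALTHY + DASH_UNHEALTHY:
        if comp not in intakes or pd.isna(intakes[comp]):
            raise MissingComponentError(f"DASH component {comp!r} missing")
        rank = int(
            _quintile_rank(np.array([float(intakes[comp])]), quint[comp])[0]
        )
        if comp in DASH_UNHEALTHY and reverse_unhealthy:
            rank = 6 - rank
        total += rank
    return total


def dash_scores(intakes: pd.DataFrame, cutoffs: ReferenceCutoffs,
                sex: pd.Series, reverse_unhealthy: bool = True) -> pd.Series:
    out = pd.Series(0, index=intakes.index, dtype=int)
    for s in sex.unique():
        mask = (sex == s).to_numpy()
        quint = cutoffs.quintiles[s]
        sub = intakes.loc[mask]
        score = np.zeros(mask.sum(), dtype=int)
        for comp in DASH_HEALTHY + DASH_UNHEALTHY:
            rank = _quintile_rank(sub[comp].to_numpy(dtype=float), quint[comp])
            if comp in DASH_UNHEALTHY and reverse_unhealthy:
                rank = 6 - rank
            score += rank
        out.loc[mask] = score
    return out


# ---------------------------------------------------------------------------
# DHD-2015
# ---------------------------------------------------------------------------

@dataclass
class DhdComponentTable:
    """Per-component scaling rules for the DHD-2015 index.

    Columns: component, direction (healthy/unhealthy), threshold (score-0
    end), cutoff (score-10 end), unit, scored (0/1).  Exactly 14 components
    are scored; the packaged defaults emulate the 2015 Dutch dietary
    guideline values and are overridable by any TSV with the same layout.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        n_scored = int((self.table["scored"] == 1).sum())
        if n_scored != 14:
            raise ValueError(f"DHD table must score exactly 14 components, "
                             f"got {n_scored}")
        scored = self.table[self.table["scored"] == 1]
        bad = scored[scored["threshold"] == scored["cutoff"]]
        if len(bad):
            raise ValueError(
                "threshold equals cut-off for scored components: "
                f"{list(bad['component'])}"
            )

    @classmethod
    def from_tsv(cls, path) -> "DhdComponentTable":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def default(cls) -> "DhdComponentTable":
        with resources.as_file(
            resources.files("dietmet.data") / "dhd_components.tsv"
        ) as p:
            return cls.from_tsv(p)

    @property
    def scored_components(self) -> list[str]:
        return list(self.table.loc[self.table["scored"] == 1, "component"])


def _dhd_component_score(x: np.ndarray, direction: str, threshold: float,
                         cutoff: float) -> np.ndarray:
    if direction == "healthy":
        frac = (x - threshold) / (cutoff - threshold)
    else:  # unhealthy: 10 at/below cutoff, 0 at/above threshold
        frac = (threshold - x) / (threshold - cutoff)
    return np.clip(10.0 * frac, 0.0, 10.0)


def dhd_score(intakes: Mapping[str, float],
              table: DhdComponentTable | None = None) -> float:
    """DHD-2015 total score (0–140) over the 14 scored components."""
    if table is None:
        table = DhdComponentTable.default()
    total = 0.0
    for _, row in table.table[table.table["scored"] == 1].iterrows():
        comp = row["component"]
        if comp not in intakes or pd.isna(intakes[comp]):
            raise MissingComponentError(f"DHD component {comp!r} missing")
        total += float(
            _dhd_component_score(
                np.array([float(intakes[comp])]), row["direction"],
                float(row["threshold"]), float(row["cutoff"]),
            )[0]
        )
    return total


def dhd_scores(intakes: pd.DataFrame,
               table: DhdComponentTable | None = None) -> pd.Series:
    if table is None:
        table = DhdComponentTable.default()
    total = np.zeros(len(intakes))
    for _, row in table.table[table.table["scored"] == 1].iterrows():
        total += _dhd_component_score(
            intakes[row["component"]].to_numpy(dtype=float), row["direction"],
            float(row["threshold"]), float(row["cutoff"]),
        )
    return pd.Series(total, index=intakes.index)


# ---------------------------------------------------------------------------
# Tertiles
# ---------------------------------------------------------------------------

def assign_tertiles(scores: pd.Series | np.ndarray) -> pd.Series:
    """Adherence tertiles 1 (low) / 2 / 3 (high).

    Boundaries at the empirical 1/3 and 2/3 quantiles; values tied with a
    boundary fall in the lower tertile.
    """
    scores = pd.Series(scores)
    vals = scores.to_numpy(dtype=float)
    if len(np.unique(vals[~np.isnan(vals)])) < 3:
        raise ValueError("tertile assignment needs at least 3 distinct values")
    q1, q2 = np.quantile(vals[~np.isnan(vals)], [1 / 3, 2 / 3])
    labels = 1 + (vals > q1).astype(int) + (vals > q2).astype(int)
    return pd.Series(labels, index=scores.index, dtype=int)


def score_cohort(
    intakes: pd.DataFrame,
    sex: pd.Series | str = "sex",
    cutoffs: ReferenceCutoffs | None = None,
    dhd_table: DhdComponentTable | None = None,
    dash_reverse_unhealthy: bool = True,
) -> pd.DataFrame:
    """All three diet scores plus tertile labels for a cohort.

    Reference cut-offs default to sex-specific statistics of the supplied
    cohort itself (the analysis cohort, i.e. post-exclusion).
    """
    if isinstance(sex, str):
        sex = intakes[sex]
    if cutoffs is None:
        cutoffs = compute_reference_cutoffs(intakes, sex)
    out = pd.DataFrame(index=intakes.index)
    out["med"] = med_scores(intakes, cutoffs, sex)
    out["dash"] = dash_scores(intakes, cutoffs, sex,
                              reverse_unhealthy=dash_reverse_unhealthy)
    out["dhd"] = dhd_scores(intakes, dhd_table)
    for name in ("med", "dash", "dhd"):
        out[f"{name}_tertile"] = assign_tertiles(out[name])
    return out


class DietScorer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: intakes + sex in, diet scores out.

    ``fit`` learns the sex-specific reference cut-offs from the supplied
    cohort; ``transform`` scores (possibly the same) participants against
    them.  Tertiles are assigned within the transformed cohort.
    """

    def __init__(self, dash_reverse_unhealthy: bool = True,
                 dhd_table: DhdComponentTable | None = None,
                 sex_col: str = "sex"):
        self.dash_reverse_unhealthy = dash_reverse_unhealthy
        self.dhd_table = dhd_table
        self.sex_col = sex_col

    def fit(self, X: pd.DataFrame, y=None):
        self.cutoffs_ = compute_reference_cutoffs(X, X[self.sex_col])
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "cutoffs_"):
            raise ValueError("DietScorer is not fitted")
        return score_cohort(
            X, X[self.sex_col], cutoffs=self.cutoffs_,
            dhd_table=self.dhd_table,
            dash_reverse_unhealthy=self.dash_reverse_unhealthy,
        )
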