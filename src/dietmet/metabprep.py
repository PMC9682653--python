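"""Metabolite-matrix preprocessing.

Stages, in enforced order:

``raw → qc → imputed → zero-replaced → ratios-recomputed → normalized``

* QC: drop the named quality-control failures (default panel: glutamine,
  pyruvate, glycerol, β-hydroxybutyrate, acetate) plus any registry-flagged
  measure, and every ratio depending on a dropped measure.
* Imputation: absolute measures only, chained iterative regression with a
  tree-ensemble learner (an ExtraTrees missForest-style imputer), at most 10
  rounds with an early tolerance stop, deterministic given the seed.
* Zero replacement: exact zeros in absolute measures become half of the
  smallest strictly positive observed value of that measure.
* Ratio recomputation: every ratio column is overwritten from its registry
  definition on the completed absolute measures (×100 for %-unit ratios).
* Normalisation: per measure, y = ln(x + P10(x)) with P10 the empirical
  10th percentile (linear interpolation), then scaled to SD units
  (mean 0, SD 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import ExtraTreesRegressor
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .registry import MeasureRegistry

STAGES = ["raw", "qc", "imputed", "zero-replaced", "ratios-recomputed",
          "normalized"]


class StageError(RuntimeError):
    """A preprocessing operation was called out of stage order."""


@dataclass
class MetaboliteMatrix:
    """Participants × measures values plus the current pipeline stage."""

    data: pd.DataFrame = field(repr=False)
    stage: str = "raw"

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    def _require(self, stage: str) -> None:
        if self.stage != stage:
            raise StageError(
                f"operation requires stage {stage!r}, matrix is at "
                f"{self.stage!r}"
            )

    def advanced(self, data: pd.DataFrame, stage: str) -> "MetaboliteMatrix":
        if STAGES.index(stage) != STAGES.index(self.stage) + 1:
            raise StageError(f"cannot jump from {self.stage!r} to {stage!r}")
        return replace(self, data=data, stage=stage)


def apply_qc_exclusions(matrix: MetaboliteMatrix, registry: MeasureRegistry
                        ) -> tuple[MetaboliteMatrix, MeasureRegistry]:
    """Drop QC-failed measures and any ratio depending on them."""
    matrix._require("raw")
    flagged = [m for m in registry.qc_failed_measures
               if m in matrix.data.columns or m in registry.measures]
    dependent = registry.ratios_depending_on(flagged)
    dropped = list(dict.fromkeys(flagged + dependent))
    reg_out = registry.drop(dropped)
    cols = [c for c in matrix.data.columns if c not in set(dropped)]
    return matrix.advanced(matrix.data[cols], "qc"), reg_out


def impute_missing(
    matrix: MetaboliteMatrix,
    registry: MeasureRegistry,
    seed: int = 0,
    n_estimators: int = 10,
    max_depth: int = 8,
    max_iter: int = 10,
    tol: float = 1e-3,
) -> MetaboliteMatrix:
    """Impute missing absolute measures by iterative tree-ensemble regression.

    Ratios are left untouched (they are recomputed later from the completed
    absolute measures).  Deterministic given ``seed``.
    """
    matrix._require("qc")
    data = matrix.data.copy()
    abs_cols = [c for c in registry.absolute_measures if c in data.columns]
    for col in abs_cols:
        if data[col].notna().sum() == 0:
            raise ValueError(f"measure {col!r} has no observed values")
    block = data[abs_cols]
    if block.isna().any().any():
        imputer = IterativeImputer(
            estimator=ExtraTreesRegressor(
                n_estimators=n_estimators, max_depth=max_depth,
                random_state=seed, n_jobs=1,
            ),
            max_iter=max_iter,
            tol=tol,
            sample_posterior=False,
            random_state=seed,
        )
        data[abs_cols] = imputer.fit_transform(block.to_numpy(dtype=float))
    return matrix.advanced(data, "imputed")


def replace_zeros(matrix: MetaboliteMatrix,
                  registry: MeasureRegistry) -> MetaboliteMatrix:
    """Exact zeros in absolute measures → half the smallest positive value."""
    matrix._require("imputed")
    data = matrix.data.copy()
    for col in registry.absolute_measures:
        if col not in data.columns:
            continue
        vals = data[col].to_numpy(dtype=float)
        positive = vals[vals > 0]
        if len(positive) == 0:
            raise ValueError(f"measure {col!r} is entirely zero")
        vals = np.where(vals == 0.0, positive.min() / 2.0, vals)
        data[col] = vals
    return matrix.advanced(data, "zero-replaced")


def recompute_ratios(matrix: MetaboliteMatrix,
                     registry: MeasureRegistry) -> MetaboliteMatrix:
    """Overwrite every ratio column from its registry definition."""
    matrix._require("zero-replaced")
    data = matrix.data.copy()
    for name in registry.ratio_measures:
        num_terms, den_terms, unit = registry.ratio_definition(name)
        num = sum(data[t].to_numpy(dtype=float) for t in num_terms)
        den = sum(data[t].to_numpy(dtype=float) for t in den_terms)
        if np.any(den <= 0):
            raise ValueError(
                f"non-positive denominator for ratio {name!r} after zero "
                "replacement"
            )
        value = num / den
        if unit == "%":
            value = value * 100.0
        data[name] = value
    return matrix.advanced(data, "ratios-recomputed")


def normalize_measures(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """ln(x + P10) per measure, then scale to SD units (mean 0, SD 1)."""
    matrix._require("ratios-recomputed")
    data = matrix.data.copy()
    if data.isna().any().any():
        raise ValueError("normalization requires a complete matrix")
    for col in data.columns:
        x = data[col].to_numpy(dtype=float)
        p10 = np.percentile(x, 10)
        shifted = x + p10
        if np.any(shifted <= 0):
            raise ValueError(f"x + P10 non-positive for measure {col!r}")
        y = np.log(shifted)
        sd = y.std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero variance after transform for {col!r}")
        data[col] = (y - y.mean()) / sd
    return matrix.advanced(data, "normalized")


def preprocess(
    matrix: pd.DataFrame | MetaboliteMatrix,
    registry: MeasureRegistry | None = None,
    seed: int = 0,
    **imputer_kwargs,
) -> tuple[MetaboliteMatrix, MeasureRegistry]:
    """Run the full stage pipeline raw → normalized."""
    if registry is None:
        registry = MeasureRegistry.default()
    if isinstance(matrix, pd.DataFrame):
        matrix = MetaboliteMatrix(matrix, "raw")
    matrix, registry = apply_qc_exclusions(matrix, registry)
    matrix = impute_missing(matrix, registry, seed=seed, **imputer_kwargs)
    matrix = replace_zeros(matrix, registry)
    matrix = recompute_ratios(matrix, registry)
    matrix = normalize_measures(matrix)
    return matrix, registry


class MetabolitePreprocessor(TransformerMixin, BaseEstimator):
    """Sklearn-style wrapper around :func:`preprocess`.

    The normalisation statistics are in-sample cohort statistics by design
    (the analysis normalises within the analysis cohort), so ``transform``
    re-runs the staged pipeline on the supplied matrix.
    """

    def __init__(self, registry: MeasureRegistry | None = None,
                 seed: int = 0):
        self.registry = registry
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None):
        self.registry_in_ = (self.registry if self.registry is not None
                             else MeasureRegistry.default())
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "registry_in_"):
            raise ValueError("MetabolitePreprocessor is not fitted")
        matrix, registry = preprocess(X, self.registry_in_, seed=self.seed)
        self.registry_out_ = registry
        self.stage_ = matrix.stage
        return matrix.data
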