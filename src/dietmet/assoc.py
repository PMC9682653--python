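"""Covariate-adjusted association screens with FDR control.

Screens link diet-score tertiles (or continuous scores), normalized
metabolite measures, the ordinal GMS score, its pairwise contrasts and
continuous glycaemic traits (HOMA-IR, HbA1c):

* proportional-odds (ordinal logistic) models for the 3-level GMS score;
* binary logistic models for the GMS pairs (0v1, 0v2, 1v2);
* ordinary least squares for continuous outcomes, with optional sex / BMI
  (≥30 vs <30) stratification and standardized betas;
* a tertile trend test that replaces the tertile dummies with each
  participant's tertile-median score as a single continuous covariate;
* exposure × modifier interaction Wald tests;
* Benjamini–Hochberg step-up FDR (one family per screen).

Crude and adjusted variants differ only by the adjustment set; Wald
confidence intervals throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.stats.multitest import multipletests

#: the full adjustment set of the adjusted models
ADJUSTMENT_COVARIATES = [
    "age", "sex", "bmi", "education", "income", "smoking", "energy_intake",
    "glucose_intake", "egfr", "physical_activity", "cvd_history",
    "lipid_med", "batch_year",
]


class FitError(RuntimeError):
    """Model could not be fit (separation, non-convergence, degeneracy)."""


def build_design(data: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    """Numeric design matrix: dummy-code categoricals (first level reference,
    'unknown' kept as its own indicator), booleans to 0/1."""
    parts = []
    for col in cols:
        s = data[col]
        if s.dtype == bool:
            parts.append(s.astype(float).rename(col))
        elif s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = [lv for lv in pd.unique(s.dropna()) if lv != "unknown"]
            levels = sorted(map(str, levels))
            if "unknown" in set(map(str, pd.unique(s.dropna()))):
                levels = levels + ["unknown"]
            if len(levels) < 2:
                continue
            for lv in levels[1:]:
                parts.append(
                    (s.astype(str) == lv).astype(float).rename(f"{col}[{lv}]")
                )
        else:
            parts.append(s.astype(float).rename(col))
    if not parts:
        return pd.DataFrame(index=data.index)
    return pd.concat(parts, axis=1)


def standardize_continuous(design: pd.DataFrame) -> pd.DataFrame:
    """Z-score non-indicator columns of a design matrix.

    Keeps 0/1 dummies untouched; rescaling continuous covariates leaves the
    exposure coefficients of interest unchanged while conditioning the
    likelihood optimisation.
    """
    out = design.copy()
    for col in out.columns:
        vals = out[col]
        uniq = pd.unique(vals.dropna())
        if len(uniq) > 2 or not set(np.asarray(uniq, dtype=float)) <= {0.0, 1.0}:
            sd = vals.std(ddof=1)
            if sd > 0:
                out[col] = (vals - vals.mean()) / sd
    return out


def _tertile_dummies(data: pd.DataFrame, tertile_col: str) -> pd.DataFrame:
    t = data[tertile_col].astype(int)
    present = sorted(t.unique())
    if len(present) < 2:
        raise FitError(
            f"exposure {tertile_col!r} has a single tertile present"
        )
    out = pd.DataFrame(index=data.index)
    for lv in (2, 3):
        if lv in present:
            out[f"{tertile_col}[T{lv}]"] = (t == lv).astype(float)
    return out


def _complete_cases(*frames) -> pd.Index:
    idx = frames[0].index
    mask = pd.Series(True, index=idx)
    for f in frames:
        mask &= f.notna().all(axis=1) if isinstance(f, pd.DataFrame) \
            else f.notna()
    return idx[mask]


@dataclass
class AssociationResult:
    """Tidy per-term fit summary.

    ``table`` has one row per exposure term: term, effect (OR or beta),
    ci_low, ci_high, p; ``q`` is filled by the screen-level FDR pass.
    """

    table: pd.DataFrame = field(repr=False)
    family: str = ""
    n: int = 0
    converged: bool = True

    def effect(self, term: str | None = None) -> float:
        tab = self.table
        row = tab.iloc[-1] if term is None else tab.set_index("term").loc[term]
        return float(row["effect"])


def _check_converged(res, context: str) -> None:
    converged = getattr(res, "mle_retvals", {}).get("converged", True)
    if not converged or not np.all(np.isfinite(res.bse)):
        raise FitError(f"{context}: model did not converge "
                       f"(retvals={getattr(res, 'mle_retvals', None)})")


def _wald_table(params, bse, pvalues, terms, exponentiate: bool) -> pd.DataFrame:
    rows = []
    for t in terms:
        est, se, p = params[t], bse[t], pvalues[t]
        lo, hi = est - 1.959963984540054 * se, est + 1.959963984540054 * se
        if exponentiate:
            est, lo, hi = np.exp(est), np.exp(lo), np.exp(hi)
        rows.append((t, est, lo, hi, p))
    return pd.DataFrame(rows, columns=["term", "effect", "ci_low", "ci_high",
                                       "p"])


def _exposure_design(data, exposure, tertile):
    if tertile:
        return _tertile_dummies(data, exposure)
    return data[[exposure]].astype(float)


def fit_proportional_odds(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    adjust: list[str] | None = None,
    tertile: bool = False,
) -> AssociationResult:
    """Proportional-odds model of the 3-level GMS score; ORs per exposure
    term (tertile contrasts vs tertile 1, or per unit/SD when continuous)."""
    expo = _exposure_design(data, exposure, tertile)
    adj = standardize_continuous(build_design(data, adjust or []))
    y = data[outcome]
    idx = _complete_cases(expo, adj, y)
    X = pd.concat([expo, adj], axis=1).loc[idx]
    yy = y.loc[idx].astype(int)
    if yy.nunique() < 3:
        raise FitError(f"outcome {outcome!r} has {yy.nunique()} levels, "
                       "proportional-odds needs 3")
    model = OrderedModel(yy, X, distr="logit")
    res = model.fit(method="bfgs", maxiter=500, disp=0)
    _check_converged(res, f"ordinal {outcome} ~ {exposure}")
    table = _wald_table(res.params, res.bse, res.pvalues, list(expo.columns),
                        exponentiate=True)
    return AssociationResult(table, family="proportional-odds", n=len(idx))


def fit_pair_logit(
    data: pd.DataFrame,
    outcome: str,
    pair: tuple[int, int],
    exposure: str,
    adjust: list[str] | None = None,
    tertile: bool = False,
) -> AssociationResult:
    """Binary logit of one GMS pair (rows filtered to the two levels)."""
    lo, hi = pair
    sub = data[data[outcome].isin([lo, hi])]
    expo = _exposure_design(sub, exposure, tertile)
    adj = standardize_continuous(build_design(sub, adjust or []))
    y = (sub[outcome] == hi).astype(float)
    idx = _complete_cases(expo, adj, y)
    if y.loc[idx].nunique() < 2:
        raise FitError(f"pair {pair} has fewer than 2 outcome classes")
    X = sm.add_constant(pd.concat([expo, adj], axis=1).loc[idx],
                        has_constant="add")
    try:
        res = sm.Logit(y.loc[idx], X).fit(method="lbfgs", maxiter=500,
                                          disp=0)
    except Exception as exc:  # perfect separation and friends
        raise FitError(f"logit pair {pair} ~ {exposure}: {exc}") from exc
    _check_converged(res, f"logit pair {pair} ~ {exposure}")
    table = _wald_table(res.params, res.bse, res.pvalues, list(expo.columns),
                        exponentiate=True)
    return AssociationResult(table, family="binary-logit", n=len(idx))


def fit_linear_assoc(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    adjust: list[str] | None = None,
    tertile: bool = False,
    stratum: pd.Series | None = None,
    standardize: bool = True,
) -> AssociationResult:
    """OLS of a continuous outcome on the exposure plus adjustment set.

    ``standardize`` z-scores the outcome and a continuous exposure within
    the analysis rows, giving standardized betas.  ``stratum`` is a boolean
    filter (e.g. sex == 'female' or bmi >= 30) applied before fitting.
    """
    sub = data if stratum is None else data[stratum.reindex(data.index)]
    expo = _exposure_design(sub, exposure, tertile)
    adj = build_design(sub, adjust or [])
    y = sub[outcome].astype(float)
    idx = _complete_cases(expo, adj, y)
    if len(idx) <= expo.shape[1] + adj.shape[1] + 1:
        raise FitError(
            f"stratum n={len(idx)} too small for "
            f"{expo.shape[1] + adj.shape[1]} regressors"
        )
    X = pd.concat([expo, adj], axis=1).loc[idx]
    yy = y.loc[idx]
    if standardize:
        yy = (yy - yy.mean()) / yy.std(ddof=1)
        if not tertile:
            for c in expo.columns:
                s = X[c]
                X[c] = (s - s.mean()) / s.std(ddof=1)
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        raise FitError(
            f"rank-deficient design ({rank} < {Xc.shape[1]}) for "
            f"{outcome} ~ {exposure}; aliased columns present"
        )
    res = sm.OLS(yy, Xc).fit()
    table = _wald_table(res.params, res.bse, res.pvalues, list(expo.columns),
                        exponentiate=False)
    return AssociationResult(table, family="linear", n=len(idx))


def trend_test(
    data: pd.DataFrame,
    outcome: str,
    tertile_col: str,
    score_col: str,
    adjust: list[str] | None = None,
    family: str = "proportional-odds",
    pair: tuple[int, int] | None = None,
) -> float:
    """P for trend: tertile dummies replaced by the per-tertile median score
    carried as a single continuous covariate."""
    medians = data.groupby(data[tertile_col].astype(int))[score_col].median()
    trend = data[tertile_col].astype(int).map(medians).astype(float)
    work = data.copy()
    work["_trend"] = trend
    if family == "proportional-odds":
        res = fit_proportional_odds(work, outcome, "_trend", adjust)
    elif family == "binary-logit":
        res = fit_pair_logit(work, outcome, pair, "_trend", adjust)
    elif family == "linear":
        res = fit_linear_assoc(work, outcome, "_trend", adjust,
                               standardize=False)
    else:
        raise ValueError(f"unknown family {family!r}")
    return float(res.table.set_index("term").loc["_trend", "p"])


def interaction_pvalue(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    modifier: str,
    adjust: list[str] | None = None,
    tertile: bool = False,
) -> float:
    """Wald p for exposure × modifier product terms added to the adjusted
    ordinal model (joint chi-square test for multi-dummy exposures)."""
    expo = _exposure_design(data, exposure, tertile)
    adjust = [a for a in (adjust or []) if a != modifier]
    mod = standardize_continuous(build_design(data, [modifier]))
    if mod.shape[1] == 0 or mod.nunique().max() < 2:
        raise FitError(f"modifier {modifier!r} is constant")
    adj = standardize_continuous(build_design(data, adjust))
    inter = pd.DataFrame(index=data.index)
    for ec in expo.columns:
        for mc in mod.columns:
            inter[f"{ec}:{mc}"] = expo[ec] * mod[mc]
    y = data[outcome]
    idx = _complete_cases(expo, mod, adj, inter, y)
    X = pd.concat([expo, mod, adj, inter], axis=1).loc[idx]
    model = OrderedModel(y.loc[idx].astype(int), X, distr="logit")
    res = model.fit(method="bfgs", maxiter=500, disp=0)
    _check_converged(res, f"interaction {exposure}x{modifier}")
    constraints = [f"{name} = 0" for name in inter.columns]
    wt = res.wald_test(", ".join(constraints), scalar=True)
    return float(wt.pvalue)


def bh_fdr(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up q-values and ``q < alpha`` flags."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q < alpha


def intersect_signatures(
    per_diet_sets: dict[str, set],
    gms_set: set,
    registry_order: list[str],
) -> list[str]:
    """Measures FDR-significant for every diet screen and for GMS,
    deterministically ordered by registry order."""
    common = None
    for s in per_diet_sets.values():
        common = set(s) if common is None else common & set(s)
    common = (common or set()) & set(gms_set)
    ordered = [m for m in registry_order if m in common]
    ordered += sorted(common - set(registry_order))
    return ordered
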