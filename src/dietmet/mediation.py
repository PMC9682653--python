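"""Sobel–Goodman mediation screening.

For each (diet score, metabolite measure, GMS outcome) triple, three
least-squares stages on identical complete-case rows:

(i)   mediator ~ exposure + covariates          → a, se_a
(ii)  outcome  ~ exposure + mediator + covariates → b, se_b, c_direct
(iii) outcome  ~ exposure + covariates          → c_total

indirect = a·b;  sobel_se = sqrt(b²·se_a² + a²·se_b²);  the Goodman
variants add (goodman1) or subtract (goodman2) se_a²·se_b² under the root.
z = indirect / sobel_se with a two-sided normal p.  Proportion mediated =
indirect / c_total, reported signed and untruncated (out-of-range values
flag inconsistent mediation).  Because the three stages share rows, the
product-of-coefficients equals the difference of coefficients exactly:
c_total = c_direct + a·b.

All stages are least squares even for the ordinal / binary outcomes,
matching the classical Sobel–Goodman procedure; the screen covers the GMS
score (0/1/2 numeric) and the three pair indicators, and the consistency
filter keeps measures whose mediation is significant with a same-signed
indirect effect in every diet × GMS-pair cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .assoc import build_design, _complete_cases, bh_fdr

GMS_PAIRS = [(0, 1), (0, 2), (1, 2)]


def pair_label(pair: tuple[int, int]) -> str:
    return f"{pair[0]}v{pair[1]}"


@dataclass
class MediationResult:
    """One Sobel–Goodman fit."""

    a: float
    se_a: float
    b: float
    se_b: float
    c_total: float
    se_c_total: float
    c_direct: float
    indirect: float
    sobel_se: float
    goodman1_se: float
    goodman2_se: float
    z: float
    p: float
    proportion_mediated: float
    n: int
    flags: tuple = ()


def _ols_coef(y: pd.Series, X: pd.DataFrame, term: str):
    res = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    return float(res.params[term]), float(res.bse[term]), res


def sobel_goodman(
    data: pd.DataFrame,
    exposure: str,
    mediator: str,
    outcome: str,
    covariates: list[str] | None = None,
    outcome_values: pd.Series | None = None,
) -> MediationResult:
    """Sobel–Goodman mediation test on complete-case rows.

    ``outcome_values`` may supply a precomputed numeric outcome (e.g. a pair
    indicator) aligned with ``data``; otherwise ``data[outcome]`` is used.
    """
    y = (outcome_values if outcome_values is not None
         else data[outcome]).astype(float)
    adj = build_design(data, covariates or [])
    cols = data[[exposure, mediator]].astype(float)
    idx = _complete_cases(cols, adj, y)
    expo = cols.loc[idx, [exposure]]
    med = cols.loc[idx, mediator]
    yy = y.loc[idx]
    C = adj.loc[idx]

    a, se_a, _ = _ols_coef(med, pd.concat([expo, C], axis=1), exposure)
    res2 = sm.OLS(
        yy,
        sm.add_constant(
            pd.concat([expo, med.rename(mediator), C], axis=1),
            has_constant="add",
        ),
    ).fit()
    b, se_b = float(res2.params[mediator]), float(res2.bse[mediator])
    c_direct = float(res2.params[exposure])
    c_total, se_c_total, _ = _ols_coef(yy, pd.concat([expo, C], axis=1),
                                       exposure)

    indirect = a * b
    sobel_var = b ** 2 * se_a ** 2 + a ** 2 * se_b ** 2
    sobel_se = np.sqrt(sobel_var)
    goodman1_se = np.sqrt(sobel_var + se_a ** 2 * se_b ** 2)
    g2_var = sobel_var - se_a ** 2 * se_b ** 2
    flags = []
    if g2_var >= 0:
        goodman2_se = np.sqrt(g2_var)
    else:
        goodman2_se = np.nan
        flags.append("goodman2_undefined")
    if sobel_se > 0:
        z = indirect / sobel_se
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        z, p = 0.0, 1.0
    if c_total == 0:
        proportion = np.nan
        flags.append("proportion_undefined")
    else:
        proportion = indirect / c_total
        if not 0 <= proportion <= 1:
            flags.append("inconsistent_mediation")
    return MediationResult(
        a=a, se_a=se_a, b=b, se_b=se_b, c_total=c_total,
        se_c_total=se_c_total, c_direct=c_direct, indirect=indirect,
        sobel_se=float(sobel_se), goodman1_se=float(goodman1_se),
        goodman2_se=float(goodman2_se), z=float(z), p=p,
        proportion_mediated=float(proportion), n=len(idx),
        flags=tuple(flags),
    )


def mediation_screen(
    data: pd.DataFrame,
    diet_cols: dict[str, str],
    measures: list[str],
    covariates: list[str] | None = None,
    gms_col: str = "gms",
    include_gms_score: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One Sobel–Goodman fit per diet × measure × outcome cell.

    Outcomes: the numeric GMS score (optional) and the three pair
    indicators (rows restricted to each pair's two levels).  BH-FDR is
    applied over the whole screen's Sobel p-values; failures in single
    cells are logged in ``status`` and do not stop the screen.
    """
    rows = []
    outcomes: list[tuple[str, tuple | None]] = []
    if include_gms_score:
        outcomes.append(("gms", None))
    outcomes += [(pair_label(p), p) for p in GMS_PAIRS]

    for diet, score_col in diet_cols.items():
        for measure in measures:
            for label, pair in outcomes:
                try:
                    if pair is None:
                        sub = data
                        yvals = None
                    else:
                        sub = data[data[gms_col].isin(pair)]
                        yvals = (sub[gms_col] == pair[1]).astype(float)
                    r = sobel_goodman(sub, score_col, measure, gms_col,
                                      covariates, outcome_values=yvals)
                    rows.append({
                        "diet": diet, "measure": measure, "outcome": label,
                        "a": r.a, "se_a": r.se_a, "b": r.b, "se_b": r.se_b,
                        "c_total": r.c_total, "c_direct": r.c_direct,
                        "indirect": r.indirect, "sobel_se": r.sobel_se,
                        "goodman1_se": r.goodman1_se,
                        "goodman2_se": r.goodman2_se, "z": r.z, "p": r.p,
                        "proportion_mediated": r.proportion_mediated,
                        "n": r.n, "flags": ";".join(r.flags), "status": "ok",
                    })
                except Exception as exc:
                    rows.append({
                        "diet": diet, "measure": measure, "outcome": label,
                        "p": np.nan, "status": f"error: {exc}",
                    })
    table = pd.DataFrame(rows)
    if len(table):
        ok = table["p"].notna()
        table["q"] = np.nan
        table["significant"] = False
        if ok.any():
            q, flags = bh_fdr(table.loc[ok, "p"].to_numpy(), alpha=alpha)
            table.loc[ok, "q"] = q
            table.loc[ok, "significant"] = flags
    return table


def consistency_filter(
    table: pd.DataFrame,
    diets: list[str] | None = None,
    alpha: float = 0.05,
    use_fdr: bool = True,
) -> list[str]:
    """Measures whose mediation holds in every diet × GMS-pair cell.

    A measure is retained iff, for all three diets and all three pairs
    (9 cells), the cell is present, significant (``q < alpha`` when
    ``use_fdr`` else raw ``p < alpha``) and the indirect effects share one
    sign.  Measures with incomplete coverage are excluded.
    """
    pairs = [pair_label(p) for p in GMS_PAIRS]
    if diets is None:
        diets = sorted(table["diet"].unique())
    cells = table[table["outcome"].isin(pairs)]
    kept = []
    for measure, grp in cells.groupby("measure", sort=False):
        need = {(d, o) for d in diets for o in pairs}
        have = set(zip(grp["diet"], grp["outcome"]))
        if not need <= have:
            continue
        grp = grp[[
            (d, o) in need for d, o in zip(grp["diet"], grp["outcome"])
        ]]
        if (grp["status"] != "ok").any():
            continue
        sig = grp["q"] < alpha if use_fdr else grp["p"] < alpha
        if not sig.all():
            continue
        signs = np.sign(grp["indirect"].to_numpy())
        if len(set(signs)) != 1 or 0 in signs:
            continue
        kept.append(measure)
    order = {m: i for i, m in enumerate(table["measure"].unique())}
    return sorted(kept, key=lambda m: order.get(m, len(order)))
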