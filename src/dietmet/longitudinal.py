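"""Seven-year incident type 2 diabetes: incidence summary and Poisson RRs.

Follow-up arrives as a long table (id, baseline_gms, year, incident) with
cumulative incident flags (once 1, stays 1).  Participants with type 2
diabetes at baseline are not in the risk set.  Relative risks per SD of a
normalized metabolite measure are estimated by Poisson log-linear
regression of the ever-incident indicator with a log person-years offset
and robust (HC0) standard errors by default; a no-offset mode matches a
plain per-person rate reading of RR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .assoc import build_design, standardize_continuous, _complete_cases, FitError

STRATUM_LABELS = {0: "NGM->T2D", 1: "prediabetes->T2D"}


def collapse_followup(followup: pd.DataFrame) -> pd.DataFrame:
    """Per-participant summary: baseline GMS, follow-up years, ever-incident
    flag and first event year (NaN if censored)."""
    grp = followup.sort_values("year").groupby("id", sort=False)
    out = grp.agg(
        baseline_gms=("baseline_gms", "first"),
        years=("year", "max"),
        event=("incident", "max"),
    )
    first_year = (
        followup[followup["incident"] == 1]
        .groupby("id", sort=False)["year"].min()
    )
    out["event_year"] = first_year.reindex(out.index)
    return out


def incidence_summary(followup: pd.DataFrame) -> pd.DataFrame:
    """Events, denominators and proportions per baseline-GMS stratum."""
    per = collapse_followup(followup)
    rows = []
    for stratum, grp in per.groupby("baseline_gms"):
        events = int(grp["event"].sum())
        denom = len(grp)
        rows.append({
            "baseline_gms": int(stratum),
            "label": STRATUM_LABELS.get(int(stratum), str(stratum)),
            "events": events,
            "n": denom,
            "proportion": events / denom if denom else 0.0,
        })
    out = pd.DataFrame(rows)
    total = {"baseline_gms": -1, "label": "total",
             "events": int(out["events"].sum()), "n": int(out["n"].sum())}
    total["proportion"] = total["events"] / total["n"] if total["n"] else 0.0
    return pd.concat([out, pd.DataFrame([total])], ignore_index=True)


@dataclass
class RRResult:
    """Relative risk of incident T2D per SD of one measure in one stratum."""

    rr: float
    ci_low: float
    ci_high: float
    p: float
    stratum: str
    n: int
    events: int


def poisson_rr(
    data: pd.DataFrame,
    measure: str,
    followup: pd.DataFrame,
    stratum: int,
    covariates: list[str] | None = None,
    offset: bool = True,
    robust: bool = True,
    id_col: str = "id",
) -> RRResult:
    """Poisson regression RR per SD of ``measure`` within one baseline
    stratum (0 = NGM, 1 = prediabetes).

    Person-years to event or censoring enter as a log offset when
    ``offset=True``.
    """
    per = collapse_followup(followup)
    per = per[per["baseline_gms"] == stratum]
    merged = data.set_index(id_col).join(per, how="inner")
    if len(merged) == 0:
        raise FitError(f"no follow-up rows for stratum {stratum}")
    events = int(merged["event"].sum())
    if events == 0:
        raise FitError(f"zero events in stratum {stratum}")
    adj = standardize_continuous(build_design(merged, covariates or []))
    z = merged[[measure]].astype(float)
    y = merged["event"].astype(float)
    idx = _complete_cases(z, adj, y)
    X = sm.add_constant(pd.concat([z, adj], axis=1).loc[idx],
                        has_constant="add")
    exposure_years = merged.loc[idx, "event_year"].fillna(
        merged.loc[idx, "years"]
    ).astype(float)
    model = sm.GLM(
        y.loc[idx], X, family=sm.families.Poisson(),
        offset=np.log(exposure_years) if offset else None,
    )
    res = model.fit(cov_type="HC0" if robust else "nonrobust")
    if not np.all(np.isfinite(res.bse)):
        raise FitError(f"Poisson fit for {measure!r} did not converge")
    coef, se = float(res.params[measure]), float(res.bse[measure])
    zc = 1.959963984540054
    return RRResult(
        rr=float(np.exp(coef)),
        ci_low=float(np.exp(coef - zc * se)),
        ci_high=float(np.exp(coef + zc * se)),
        p=float(res.pvalues[measure]),
        stratum=STRATUM_LABELS.get(stratum, str(stratum)),
        n=int(len(idx)),
        events=int(y.loc[idx].sum()),
    )


def rr_report(
    data: pd.DataFrame,
    measures: list[str],
    followup: pd.DataFrame,
    covariates: list[str] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Two-stratum RR table (NGM→T2D and prediabetes→T2D) per measure."""
    rows = []
    for stratum in (0, 1):
        for measure in measures:
            try:
                r = poisson_rr(data, measure, followup, stratum,
                               covariates, **kwargs)
                rows.append({
                    "stratum": r.stratum, "measure": measure, "rr": r.rr,
                    "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p,
                    "n": r.n, "events": r.events, "status": "ok",
                })
            except FitError as exc:
                rows.append({
                    "stratum": STRATUM_LABELS[stratum], "measure": measure,
                    "status": f"error: {exc}",
                })
    return pd.DataFrame(rows)
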