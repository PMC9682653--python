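"""End-to-end orchestration: ingest → scores → prep → screens → mediation →
longitudinal → reports.

A :class:`RunConfig` fully determines a run (config hash + seed are written
to the manifest; identical configs re-produce byte-identical tables).  The
stage order follows the analysis plan: cohort exclusions and covariate
imputation, diet-index scoring with in-cohort reference cut-offs,
metabolite preprocessing, diet→GMS and diet/GMS→metabolite screens with
per-screen BH-FDR, signature intersection, Sobel–Goodman mediation with the
all-cells consistency filter, and Poisson relative risks on follow-up.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import assoc, cohort as cohort_mod, dietscores, longitudinal, \
    mediation, metabprep, synth
from .registry import MeasureRegistry

DIETS = ["med", "dash", "dhd"]


@dataclass
class RunConfig:
    """One pipeline run."""

    sim: synth.SimConfig | None = None
    participants_path: str | None = None
    metabolites_path: str | None = None
    registry_path: str | None = None
    adjust: list = field(
        default_factory=lambda: list(assoc.ADJUSTMENT_COVARIATES)
    )
    alpha: float = 0.05
    seed: int = 0
    dash_reverse_unhealthy: bool = True
    mediation_use_fdr: bool = True
    poisson_offset: bool = True
    screen_gms_pairs: bool = True
    run_interactions: bool = False
    outdir: str | None = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise synth.ConfigError(f"alpha must be in (0,1), got {self.alpha}")
        if self.sim is None and (self.participants_path is None
                                 or self.metabolites_path is None):
            raise synth.ConfigError(
                "either sim or participants_path+metabolites_path required"
            )

    def hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)
        if self.sim is not None:
            payload["sim"] = dataclasses.asdict(self.sim)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All report tables of one run, plus audit and manifest."""

    diet_gms: pd.DataFrame = None
    traits: pd.DataFrame = None
    diet_metabolites: pd.DataFrame = None
    gms_metabolites: pd.DataFrame = None
    mediation_table: pd.DataFrame = None
    rr_table: pd.DataFrame = None
    incidence: pd.DataFrame = None
    signature: list = field(default_factory=list)
    candidates: list = field(default_factory=list)
    audit: cohort_mod.ExclusionAudit = None
    manifest: dict = field(default_factory=dict)
    frame: pd.DataFrame = field(default=None, repr=False)

    def write(self, outdir) -> None:
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "diet_gms.tsv": self.diet_gms,
            "traits.tsv": self.traits,
            "diet_metabolites.tsv": self.diet_metabolites,
            "gms_metabolites.tsv": self.gms_metabolites,
            "mediation.tsv": self.mediation_table,
            "relative_risk.tsv": self.rr_table,
            "incidence.tsv": self.incidence,
        }
        for name, tab in tables.items():
            if tab is not None:
                tab.to_csv(out / name, sep="\t", index=False,
                           float_format="%.10g")
        if self.audit is not None:
            self.audit.to_json(out / "exclusion_audit.json")
        with open(out / "signature.json", "w") as fh:
            json.dump({"stable_signature": self.signature,
                       "candidates": self.candidates}, fh, indent=2)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2)


def _load_inputs(cfg: RunConfig):
    if cfg.sim is not None:
        explicit = (MeasureRegistry.from_tsv(cfg.registry_path)
                    if cfg.registry_path else None)
        registry = synth.build_registry(cfg.sim, explicit)
        participants, matrix, truth = synth.generate_cohort(cfg.sim, registry)
        return participants, matrix, registry, truth
    participants = pd.read_csv(cfg.participants_path, sep="\t")
    matrix = pd.read_csv(cfg.metabolites_path, sep="\t")
    matrix.index = participants.index
    registry = (MeasureRegistry.from_tsv(cfg.registry_path)
                if cfg.registry_path else MeasureRegistry.default())
    return participants, matrix, registry, None


def _screen_diet_gms(frame, cfg) -> pd.DataFrame:
    rows = []
    for diet in DIETS:
        tcol = f"{diet}_tertile"
        for label, adj in (("crude", []), ("adjusted", cfg.adjust)):
            try:
                r = assoc.fit_proportional_odds(frame, "gms", tcol, adj,
                                                tertile=True)
                for _, term in r.table.iterrows():
                    rows.append({"diet": diet, "outcome": "gms",
                                 "model": label, "term": term["term"],
                                 "or": term["effect"],
                                 "ci_low": term["ci_low"],
                                 "ci_high": term["ci_high"], "p": term["p"],
                                 "n": r.n, "status": "ok"})
                ptrend = assoc.trend_test(frame, "gms", tcol, diet, adj,
                                          family="proportional-odds")
                rows.append({"diet": diet, "outcome": "gms", "model": label,
                             "term": "trend", "p": ptrend, "status": "ok"})
            except Exception as exc:
                rows.append({"diet": diet, "outcome": "gms", "model": label,
                             "status": f"error: {exc}"})
            for pair in mediation.GMS_PAIRS:
                try:
                    r = assoc.fit_pair_logit(frame, "gms", pair, tcol, adj,
                                             tertile=True)
                    for _, term in r.table.iterrows():
                        rows.append({
                            "diet": diet,
                            "outcome": mediation.pair_label(pair),
                            "model": label, "term": term["term"],
                            "or": term["effect"], "ci_low": term["ci_low"],
                            "ci_high": term["ci_high"], "p": term["p"],
                            "n": r.n, "status": "ok",
                        })
                except Exception as exc:
                    rows.append({
                        "diet": diet, "outcome": mediation.pair_label(pair),
                        "model": label, "status": f"error: {exc}",
                    })
        if cfg.run_interactions:
            for modifier in ("sex", "bmi"):
                try:
                    p = assoc.interaction_pvalue(frame, "gms", tcol,
                                                 modifier, cfg.adjust,
                                                 tertile=True)
                    rows.append({"diet": diet, "outcome": "gms",
                                 "model": "interaction", "term": modifier,
                                 "p": p, "status": "ok"})
                except Exception as exc:
                    rows.append({"diet": diet, "outcome": "gms",
                                 "model": "interaction", "term": modifier,
                                 "status": f"error: {exc}"})
    return pd.DataFrame(rows)


def _screen_traits(frame, cfg) -> pd.DataFrame:
    rows = []
    strata = {
        "overall": None,
        "male": frame["sex"] == "male",
        "female": frame["sex"] == "female",
        "obese": frame["bmi"] >= 30,
        "non_obese": frame["bmi"] < 30,
    }
    for trait in ("homa_ir", "hba1c"):
        if trait not in frame.columns:
            continue
        for diet in DIETS:
            for sname, mask in strata.items():
                adj = [a for a in cfg.adjust
                       if not (sname in ("male", "female") and a == "sex")]
                try:
                    r = assoc.fit_linear_assoc(frame, trait, diet, adj,
                                               stratum=mask)
                    term = r.table.iloc[0]
                    rows.append({"trait": trait, "diet": diet,
                                 "stratum": sname, "beta": term["effect"],
                                 "ci_low": term["ci_low"],
                                 "ci_high": term["ci_high"], "p": term["p"],
                                 "n": r.n, "status": "ok"})
                except Exception as exc:
                    rows.append({"trait": trait, "diet": diet,
                                 "stratum": sname,
                                 "status": f"error: {exc}"})
    return pd.DataFrame(rows)


def _screen_diet_metabolites(frame, measures, cfg) -> pd.DataFrame:
    rows = []
    for diet in DIETS:
        for m in measures:
            try:
                r = assoc.fit_linear_assoc(frame, m, diet, cfg.adjust)
                term = r.table.iloc[0]
                rows.append({"diet": diet, "measure": m,
                             "beta": term["effect"],
                             "ci_low": term["ci_low"],
                             "ci_high": term["ci_high"],
                             "p": term["p"], "n": r.n, "status": "ok"})
            except Exception as exc:
                rows.append({"diet": diet, "measure": m, "p": np.nan,
                             "status": f"error: {exc}"})
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    table["significant"] = False
    for diet in DIETS:  # one FDR family per diet screen
        mask = (table["diet"] == diet) & table["p"].notna()
        if mask.any():
            q, flags = assoc.bh_fdr(table.loc[mask, "p"].to_numpy(),
                                    alpha=cfg.alpha)
            table.loc[mask, "q"] = q
            table.loc[mask, "significant"] = flags
    return table


def _screen_gms_metabolites(frame, measures, cfg) -> pd.DataFrame:
    rows = []
    for m in measures:
        try:
            r = assoc.fit_proportional_odds(frame, "gms", m, cfg.adjust)
            term = r.table.iloc[0]
            rows.append({"measure": m, "outcome": "gms",
                         "or": term["effect"], "ci_low": term["ci_low"],
                         "ci_high": term["ci_high"], "p": term["p"],
                         "n": r.n, "status": "ok"})
        except Exception as exc:
            rows.append({"measure": m, "outcome": "gms", "p": np.nan,
                         "status": f"error: {exc}"})
        if cfg.screen_gms_pairs:
            for pair in mediation.GMS_PAIRS:
                try:
                    r = assoc.fit_pair_logit(frame, "gms", pair, m,
                                             cfg.adjust)
                    term = r.table.iloc[0]
                    rows.append({
                        "measure": m, "outcome": mediation.pair_label(pair),
                        "or": term["effect"], "ci_low": term["ci_low"],
                        "ci_high": term["ci_high"], "p": term["p"],
                        "n": r.n, "status": "ok",
                    })
                except Exception as exc:
                    rows.append({
                        "measure": m, "outcome": mediation.pair_label(pair),
                        "p": np.nan, "status": f"error: {exc}",
                    })
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    table["significant"] = False
    mask = (table["outcome"] == "gms") & table["p"].notna()
    if mask.any():  # FDR family: the ordinal screen across measures
        q, flags = assoc.bh_fdr(table.loc[mask, "p"].to_numpy(),
                                alpha=cfg.alpha)
        table.loc[mask, "q"] = q
        table.loc[mask, "significant"] = flags
    return table


def run_pipeline(cfg: RunConfig,
                 write: bool | None = None) -> ReportBundle:
    """Execute every stage and return (optionally write) the report bundle."""
    participants, matrix, registry, truth = _load_inputs(cfg)

    cohort, audit = cohort_mod.apply_exclusion_cascade(participants, matrix)
    covars_present = [c for c in cfg.adjust if c in cohort.columns]
    covars_complete = cohort[covars_present].notna().all(axis=1)
    cohort = cohort_mod.impute_covariates(cohort)

    scores = dietscores.score_cohort(
        cohort, cohort["sex"],
        dash_reverse_unhealthy=cfg.dash_reverse_unhealthy,
    )
    prepped, reg_out = metabprep.preprocess(
        matrix.loc[cohort.index], registry, seed=cfg.seed
    )
    measures = list(prepped.data.columns)
    frame = pd.concat([cohort, scores, prepped.data], axis=1)
    frame["_covars_complete"] = covars_complete

    diet_gms = _screen_diet_gms(frame, cfg)
    traits = _screen_traits(frame, cfg)
    diet_met = _screen_diet_metabolites(frame, measures, cfg)
    gms_met = _screen_gms_metabolites(frame, measures, cfg)

    diet_sets = {
        diet: set(diet_met.loc[(diet_met["diet"] == diet)
                               & diet_met["significant"], "measure"])
        for diet in DIETS
    }
    gms_set = set(gms_met.loc[(gms_met["outcome"] == "gms")
                              & gms_met["significant"], "measure"])
    candidates = assoc.intersect_signatures(diet_sets, gms_set, measures)

    med_table = mediation.mediation_screen(
        frame, {d: d for d in DIETS}, candidates, cfg.adjust,
        alpha=cfg.alpha,
    )
    signature = mediation.consistency_filter(
        med_table, DIETS, alpha=cfg.alpha, use_fdr=cfg.mediation_use_fdr,
    ) if len(med_table) else []

    rr_table = incidence = None
    if cfg.sim is not None:
        rr_measure = cfg.sim.rr_measure if cfg.sim.rr_measure in measures \
            else (signature[0] if signature else None)
        if rr_measure is not None:
            followup = synth.generate_followup(
                frame, frame[rr_measure], years=cfg.sim.followup_years,
                incidence_rr=cfg.sim.incidence_rr,
                seed=(cfg.seed + 101) % (2 ** 31),
            )
            incidence = longitudinal.incidence_summary(followup)
            rr_measures = signature if signature else [rr_measure]
            rr_table = longitudinal.rr_report(
                frame, rr_measures, followup, cfg.adjust,
                offset=cfg.poisson_offset,
            )

    bundle = ReportBundle(
        diet_gms=diet_gms, traits=traits, diet_metabolites=diet_met,
        gms_metabolites=gms_met, mediation_table=med_table,
        rr_table=rr_table, incidence=incidence, signature=signature,
        candidates=candidates, audit=audit,
        manifest={
            "config_hash": cfg.hash(),
            "seed": cfg.seed,
            "alpha": cfg.alpha,
            "n_cohort": len(cohort),
            "n_measures": len(measures),
            "adjust": covars_present,
            "truth": json.loads(truth.to_json()) if truth else None,
        },
        frame=frame,
    )
    if write is None:
        write = cfg.outdir is not None
    if write:
        bundle.write(cfg.outdir)
    return bundle


def sensitivity_rerun(cfg: RunConfig,
                      main: ReportBundle | None = None) -> ReportBundle:
    """Re-run on the restricted cohort: drop participants with incomplete
    covariate data and those with newly diagnosed T2D at baseline; returns
    the sensitivity bundle with a main-vs-sensitivity comparison in its
    manifest."""
    if main is None:
        main = run_pipeline(cfg, write=False)
    frame = main.frame
    keep = frame["_covars_complete"].astype(bool)
    if "newly_diagnosed_t2d" in frame.columns:
        keep &= ~frame["newly_diagnosed_t2d"].fillna(False).astype(bool)
    restricted = frame.loc[keep]
    if len(restricted) < 50:
        raise synth.ConfigError(
            f"restricted cohort too small (n={len(restricted)})"
        )

    sub = RunConfig(**{**dataclasses.asdict(cfg), "sim": cfg.sim,
                       "outdir": None})
    # reuse the already-prepared frame: only re-run the model stages
    measures = [c for c in main.diet_metabolites["measure"].unique()]
    diet_gms = _screen_diet_gms(restricted, sub)
    traits = _screen_traits(restricted, sub)
    diet_met = _screen_diet_metabolites(restricted, measures, sub)
    gms_met = _screen_gms_metabolites(restricted, measures, sub)
    diet_sets = {
        diet: set(diet_met.loc[(diet_met["diet"] == diet)
                               & diet_met["significant"], "measure"])
        for diet in DIETS
    }
    gms_set = set(gms_met.loc[(gms_met["outcome"] == "gms")
                              & gms_met["significant"], "measure"])
    candidates = assoc.intersect_signatures(diet_sets, gms_set, measures)
    med_table = mediation.mediation_screen(
        restricted, {d: d for d in DIETS}, candidates, sub.adjust,
        alpha=sub.alpha,
    )
    signature = mediation.consistency_filter(
        med_table, DIETS, alpha=sub.alpha, use_fdr=sub.mediation_use_fdr,
    ) if len(med_table) else []

    comparison = {
        "n_main": int(len(frame)),
        "n_sensitivity": int(len(restricted)),
        "n_dropped_incomplete_covariates":
            int((~frame["_covars_complete"].astype(bool)).sum()),
        "n_dropped_newly_diagnosed":
            int(frame.get("newly_diagnosed_t2d",
                          pd.Series(False, index=frame.index))
                .fillna(False).astype(bool).sum()),
        "signature_main": main.signature,
        "signature_sensitivity": signature,
    }
    return ReportBundle(
        diet_gms=diet_gms, traits=traits, diet_metabolites=diet_met,
        gms_metabolites=gms_met, mediation_table=med_table,
        signature=signature, candidates=candidates, audit=main.audit,
        manifest={**main.manifest, "sensitivity": comparison},
        frame=restricted,
    )
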