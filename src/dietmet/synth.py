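"""Synthetic cohort generator with planted diet → metabolite → GMS structure.

The generator emulates the statistical shape the downstream analysis
assumes, so every stage is testable without access to the (non-public)
source cohort:

* right-skewed food-component intakes (per-component log-normal with
  sex-specific medians), driven by a latent "healthiness" factor so the
  three diet indices are positively correlated;
* a targeted NMR-style measure panel from a :class:`MeasureRegistry`
  (absolute measures log-normal, ratios computed from their definitions),
  with MCAR missingness and exact zeros;
* planted mediation: the standardized MED score computed from the generated
  intakes is the exposure Z; each planted mediator satisfies
  ``M = a·Z + noise`` on the z-scale, and the ordinal GMS liability is
  ``L = Σ b_j·M_j + c_direct·Z + covariate terms + N(0,1)``, thresholded at
  two cut-points (defaults placed so the NGM/prediabetes/T2D mix is
  ≈ 57/15/28%);
* fasting plasma glucose and medication flags drawn consistently with the
  planted GMS class, so the FPG/medication classifier reproduces it;
* the five-rule exclusion cascade planted as actual data conditions with
  mutually exclusive, exactly countable rule hits;
* yearly follow-up with a per-SD planted relative risk of incident type 2
  diabetes.

Everything is deterministic given ``(config, seed)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import dietscores
from .registry import MeasureRegistry

#: direction each intake component takes w.r.t. the latent healthiness factor
COMPONENT_DIRECTION = {
    "vegetables": 1, "legumes": 1, "fruits_nuts": 1, "fish": 1, "cereals": 1,
    "mufa_pufa_sfa": 1, "fruits": 1, "nuts_legumes": 1, "wholegrain": 1,
    "low_fat_dairy": 1, "nuts": 1, "tea": 1,
    "meat": -1, "dairy": -1, "red_processed_meat": -1, "sugar_beverages": -1,
    "sodium": -1, "fats_oils": -1, "red_meat": -1, "processed_meat": -1,
    "sweet_beverages": -1, "salt": -1,
    "alcohol": 0, "coffee": 0,
}

#: female median intake per component (g/day unless noted); males ×1.2
DEFAULT_INTAKE_MEDIANS = {
    "vegetables": 130.0, "legumes": 8.0, "fruits_nuts": 140.0, "fish": 15.0,
    "cereals": 180.0, "mufa_pufa_sfa": 1.2, "meat": 95.0, "dairy": 300.0,
    "fruits": 125.0, "nuts_legumes": 20.0, "wholegrain": 80.0,
    "low_fat_dairy": 150.0, "red_processed_meat": 85.0,
    "sugar_beverages": 100.0, "sodium": 2.4, "nuts": 10.0, "tea": 300.0,
    "fats_oils": 35.0, "red_meat": 55.0, "processed_meat": 35.0,
    "sweet_beverages": 90.0, "salt": 6.5, "coffee": 3.0,
}

#: default measures carrying the planted mediation signal (absolute measures;
#: registry ratios built on them inherit it)
DEFAULT_MEDIATOR_MEASURES = ["apoa1", "dha", "isoleucine", "faw3", "ldl_c"]

DEFAULT_EXCLUSION_COUNTS = (48, 43, 168, 69, 38)

#: per-year baseline incidence of T2D by baseline GMS stratum
DEFAULT_BASE_RATES = {0: 0.0017, 1: 0.024}


class ConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort."""

    n_raw: int = 3807
    seed: int = 0
    a_diet_metab: float | tuple = 0.35
    b_metab_gms: float | tuple = -0.25
    c_direct: float = -0.3
    cov_effects: dict = field(default_factory=lambda: {
        "age_z": 0.5, "bmi_z": 0.6, "sex_female": -0.4,
    })
    n_mediators: int = 5
    n_null: int = 20
    missing_rate: float = 0.01
    zero_rate: float = 0.005
    exclusion_counts: tuple = DEFAULT_EXCLUSION_COUNTS
    gms_thresholds: tuple | None = None  # None -> 57/15/28% empirical cuts
    gms_target_props: tuple = (0.57, 0.15, 0.28)
    followup_years: int = 7
    incidence_rr: float = 1.0
    rr_measure: str = "apoa1"
    use_registry: bool = True
    mediator_measures: tuple = tuple(DEFAULT_MEDIATOR_MEASURES)
    intake_signal: float = 0.5      # loading of healthiness factor on intakes
    intake_log_sd: float = 0.5      # log-scale intake dispersion
    measure_log_sd: float = 0.25    # log-scale metabolite dispersion
    low_rank_corr: float = 0.0      # shared-factor loading on null measures
    med_fraction_t2d: float = 0.5   # T2D on hypoglycaemic medication
    newly_diagnosed_count: int = 135
    covariate_missing: dict = field(default_factory=lambda: {
        "smoking": 0.0128, "education": 0.0195, "income": 0.0402,
        "cvd_history": 0.0166, "physical_activity": 0.0746,
    })

    def __post_init__(self):
        if self.n_raw < sum(self.exclusion_counts):
            raise ConfigError(
                "n_raw must be at least sum(exclusion_counts): "
                f"{self.n_raw} < {sum(self.exclusion_counts)}"
            )
        for name in ("missing_rate", "zero_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if any(c < 0 for c in self.exclusion_counts):
            raise ConfigError("exclusion_counts must be non-negative")
        if self.gms_thresholds is not None:
            t1, t2 = self.gms_thresholds
            if not t1 < t2:
                raise ConfigError(
                    f"gms_thresholds must be strictly increasing, got "
                    f"({t1}, {t2})"
                )
        if self.followup_years < 1:
            raise ConfigError("followup_years must be >= 1")
        if self.incidence_rr <= 0:
            raise ConfigError("incidence_rr must be positive")
        if self.n_mediators < 0 or self.n_null < 0:
            raise ConfigError("n_mediators and n_null must be non-negative")

    def a_vector(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.a_diet_metab, dtype=float), (self.n_mediators,)
        ).copy()

    def b_vector(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.b_metab_gms, dtype=float), (self.n_mediators,)
        ).copy()


@dataclass
class SimTruth:
    """Planted parameters, for recovery tests."""

    mediator_names: list
    a: list
    b: list
    c_direct: float
    proportion_mediated: list
    exclusion_counts: tuple
    incidence_rr: float
    rr_measure: str
    gms_thresholds: tuple

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def planted_proportions(a: np.ndarray, b: np.ndarray,
                        c_direct: float) -> np.ndarray:
    """Per-mediator proportion mediated of the generating linear system:
    a_j·b_j / (c_direct + Σ_k a_k·b_k)."""
    total = c_direct + float(np.sum(a * b))
    if total == 0:
        return np.full(len(a), np.nan)
    return a * b / total


def _simple_registry(mediators: list[str], nulls: list[str]) -> MeasureRegistry:
    """Minimal all-absolute registry for the fast (non-panel) mode."""
    names = mediators + nulls
    tab = pd.DataFrame({
        "name": names,
        "cluster": "lipids-fa-lmw",
        "is_ratio": 0,
        "numerator": "",
        "denominator": "",
        "unit": "mmol/l",
        "qc_failed": 0,
    })
    return MeasureRegistry(tab)


def build_registry(cfg: SimConfig,
                   registry: MeasureRegistry | None = None) -> MeasureRegistry:
    """The measure registry a config's cohort is generated against."""
    if cfg.use_registry:
        return registry if registry is not None else MeasureRegistry.default()
    mediators = _mediator_names(cfg, None)
    nulls = [f"null_{j + 1:03d}" for j in range(cfg.n_null)]
    return _simple_registry(mediators, nulls)


def _draw_participants(cfg: SimConfig, rng: np.random.Generator
                       ) -> pd.DataFrame:
    n = cfg.n_raw
    sex = np.where(rng.random(n) < 0.49, "female", "male")
    df = pd.DataFrame({
        "id": [f"P{i:05d}" for i in range(n)],
        "sex": sex,
        "age": np.clip(rng.normal(60.1, 8.2, n), 40, 75),
        "bmi": np.clip(rng.normal(27.1, 4.5, n), 16, 50),
        "ethnicity": "caucasian",
    })
    df["education"] = rng.choice(["low", "middle", "high"], n,
                                 p=[0.34, 0.27, 0.39])
    df["income"] = rng.choice(["low", "middle", "high"], n,
                              p=[0.32, 0.44, 0.24])
    df["smoking"] = rng.choice(["never", "former", "current"], n,
                               p=[0.35, 0.52, 0.13])
    df["physical_activity"] = np.exp(rng.normal(np.log(12.75), 0.5, n))
    df["egfr"] = np.clip(rng.normal(80.0, 15.7, n), 20, 140)
    df["glucose_intake"] = np.clip(rng.normal(15.2, 5.0, n), 1, 60)
    df["cvd_history"] = np.where(rng.random(n) < 0.17, "yes", "no")
    df["lipid_med"] = rng.random(n) < 0.36
    df["batch_year"] = rng.choice([2014, 2016], n)
    # energy drawn inside the sex-specific plausibility window
    kcal = rng.normal(2172.0, 603.0, n)
    lo = np.where(sex == "male", 810.0, 510.0)
    hi = np.where(sex == "male", 4190.0, 3490.0)
    df["energy_intake"] = np.clip(kcal, lo, hi)
    return df


def _draw_intakes(cfg: SimConfig, rng: np.random.Generator,
                  sex: np.ndarray, h: np.ndarray) -> pd.DataFrame:
    n = len(sex)
    male = sex == "male"
    out = {}
    for comp, median in DEFAULT_INTAKE_MEDIANS.items():
        direction = COMPONENT_DIRECTION[comp]
        mu = np.log(median) + np.where(male, np.log(1.2), 0.0)
        eps = rng.normal(size=n)
        lam = cfg.intake_signal * direction
        z = lam * h + np.sqrt(max(1.0 - lam ** 2, 0.0)) * eps
        out[comp] = np.exp(mu + cfg.intake_log_sd * z)
    # alcohol: zero-inflated, higher male median, orthogonal to healthiness
    alc = np.exp(rng.normal(np.where(male, np.log(12.0), np.log(6.0)), 0.9))
    alc[rng.random(n) < 0.2] = 0.0
    out["alcohol"] = alc
    return pd.DataFrame(out)


def _mediator_names(cfg: SimConfig, registry: MeasureRegistry | None
                    ) -> list[str]:
    if cfg.use_registry:
        names = list(cfg.mediator_measures)[: cfg.n_mediators]
        if len(names) < cfg.n_mediators:
            raise ConfigError(
                "mediator_measures must name at least n_mediators measures"
            )
        if registry is not None:
            missing = set(names) - set(registry.absolute_measures)
            if missing:
                raise ConfigError(
                    f"mediator_measures not absolute measures in registry: "
                    f"{sorted(missing)}"
                )
        return names
    return [f"mediator_{j + 1:02d}" for j in range(cfg.n_mediators)]


def _draw_measure_panel(
    cfg: SimConfig,
    rng: np.random.Generator,
    registry: MeasureRegistry,
    mediator_z: pd.DataFrame,
) -> pd.DataFrame:
    """Raw (pre-QC) measure matrix: absolutes log-normal, ratios computed."""
    n = len(mediator_z)
    data = {}
    shared = rng.normal(size=n)
    r = cfg.low_rank_corr
    for name in registry.absolute_measures:
        scale = np.exp(rng.normal(0.0, 0.8))
        if name in mediator_z.columns:
            z = mediator_z[name].to_numpy()
        else:
            z = r * shared + np.sqrt(1 - r ** 2) * rng.normal(size=n)
        data[name] = scale * np.exp(cfg.measure_log_sd * z)
    df = pd.DataFrame(data)
    for name in registry.ratio_measures:
        num_terms, den_terms, unit = registry.ratio_definition(name)
        num = sum(df[t].to_numpy() for t in num_terms)
        den = sum(df[t].to_numpy() for t in den_terms)
        value = num / den
        if unit == "%":
            value = value * 100.0
        df[name] = value
    return df


def _inject_missing_and_zeros(cfg: SimConfig, rng: np.random.Generator,
                              matrix: pd.DataFrame,
                              registry: MeasureRegistry) -> pd.DataFrame:
    out = matrix.copy()
    for col in registry.absolute_measures:
        if col not in out.columns:
            continue
        n = len(out)
        if cfg.zero_rate > 0:
            zeros = rng.random(n) < cfg.zero_rate
            out.loc[zeros, col] = 0.0
        if cfg.missing_rate > 0:
            miss = rng.random(n) < cfg.missing_rate
            out.loc[miss, col] = np.nan
    return out


def plant_exclusion_conditions(
    participants: pd.DataFrame,
    metabolites: pd.DataFrame,
    counts,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Corrupt exactly ``counts[k]`` records per exclusion rule.

    Rule hits are mutually exclusive (disjoint record sets, each record fails
    exactly one rule) and are realised as the actual data condition the
    cascade tests for, so the printed cascade arithmetic is exactly
    checkable.
    """
    counts = tuple(int(c) for c in counts)
    if any(c < 0 for c in counts):
        raise ConfigError("exclusion counts must be non-negative")
    if sum(counts) > len(participants):
        raise ConfigError(
            f"exclusion counts sum to {sum(counts)} > n_raw "
            f"{len(participants)}"
        )
    participants = participants.copy()
    metabolites = metabolites.copy()
    chosen = rng.choice(len(participants), size=sum(counts), replace=False)
    groups = np.split(chosen, np.cumsum(counts)[:-1])
    planted = {}
    rule_names = ["no_metabolites", "no_gms", "implausible_energy",
                  "incomplete_diet", "non_caucasian"]
    for rule, idx in zip(rule_names, groups):
        rows = participants.index[idx]
        planted[rule] = list(rows)
        if rule == "no_metabolites":
            metabolites.loc[rows, :] = np.nan
        elif rule == "no_gms":
            participants.loc[rows, "fpg"] = np.nan
            participants.loc[rows, "fingerprick_fpg"] = np.nan
            participants.loc[rows, "on_hypoglycemic_meds"] = False
            participants.loc[rows, "uses_insulin"] = False
        elif rule == "implausible_energy":
            male = participants.loc[rows, "sex"] == "male"
            high = rng.random(len(rows)) < 0.5
            kcal = np.where(
                high, np.where(male, 4500.0, 3800.0),
                np.where(male, 600.0, 400.0),
            )
            participants.loc[rows, "energy_intake"] = kcal
        elif rule == "incomplete_diet":
            participants.loc[rows, "vegetables"] = np.nan
        elif rule == "non_caucasian":
            participants.loc[rows, "ethnicity"] = "other"
    return participants, metabolites, planted


def generate_cohort(
    config: SimConfig,
    registry: MeasureRegistry | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate (participant table, raw metabolite matrix, truth sidecar)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    participants = _draw_participants(cfg, rng)
    n = len(participants)
    h = rng.normal(size=n)
    intakes = _draw_intakes(cfg, rng, participants["sex"].to_numpy(), h)
    participants = pd.concat([participants, intakes], axis=1)

    # exposure: the standardized MED score computed from generated intakes
    cutoffs = dietscores.compute_reference_cutoffs(
        participants, participants["sex"]
    )
    med = dietscores.med_scores(participants, cutoffs, participants["sex"])
    z = (med - med.mean()) / med.std(ddof=1)
    z = z.to_numpy()

    # planted mediators on the z-scale
    a = cfg.a_vector()
    b = cfg.b_vector()
    mediator_names = _mediator_names(
        cfg, registry if cfg.use_registry else None
    )
    mz = {}
    for j, name in enumerate(mediator_names):
        noise_sd = np.sqrt(max(1.0 - a[j] ** 2, 0.05))
        mz[name] = a[j] * z + noise_sd * rng.normal(size=n)
    mediator_z = pd.DataFrame(mz, index=participants.index)

    # covariate terms on the liability scale
    cov = np.zeros(n)
    age_z = (participants["age"] - participants["age"].mean()) / \
        participants["age"].std(ddof=1)
    bmi_z = (participants["bmi"] - participants["bmi"].mean()) / \
        participants["bmi"].std(ddof=1)
    female = (participants["sex"] == "female").astype(float)
    cov_terms = {"age_z": age_z.to_numpy(), "bmi_z": bmi_z.to_numpy(),
                 "sex_female": female.to_numpy()}
    for key, effect in cfg.cov_effects.items():
        if key not in cov_terms:
            raise ConfigError(f"unknown covariate in cov_effects: {key!r}")
        cov += effect * cov_terms[key]

    liability = (
        mediator_z.to_numpy() @ b + cfg.c_direct * z + cov
        + rng.normal(size=n)
    )
    if cfg.gms_thresholds is None:
        p0, p1, _ = cfg.gms_target_props
        thresholds = tuple(np.quantile(liability, [p0, p0 + p1]))
    else:
        thresholds = tuple(cfg.gms_thresholds)
    gms = (
        (liability > thresholds[0]).astype(int)
        + (liability > thresholds[1]).astype(int)
    )

    # medication and FPG consistent with the planted class
    meds = np.zeros(n, dtype=bool)
    t2d_idx = np.flatnonzero(gms == 2)
    n_meds = int(round(cfg.med_fraction_t2d * len(t2d_idx)))
    meds[rng.choice(t2d_idx, size=n_meds, replace=False)] = True
    insulin = meds & (rng.random(n) < 0.2)

    fpg = np.empty(n)
    ngm = gms == 0
    pre = gms == 1
    t2d = gms == 2
    fpg[ngm] = np.clip(rng.normal(5.18, 0.42, ngm.sum()), 3.5, 6.09)
    fpg[pre] = np.clip(rng.normal(6.4, 0.25, pre.sum()), 6.1, 6.9)
    fpg[t2d & meds] = np.clip(rng.normal(7.5, 1.5, (t2d & meds).sum()),
                              5.0, 13.0)
    fpg[t2d & ~meds] = np.clip(rng.normal(7.9, 1.2, (t2d & ~meds).sum()),
                               7.0, 13.0)
    participants["fpg"] = fpg
    participants["on_hypoglycemic_meds"] = meds
    participants["uses_insulin"] = insulin
    participants["fingerprick_fpg"] = np.where(
        insulin | (fpg > 11.0), fpg, np.nan
    )
    participants["gms"] = gms

    # newly diagnosed at baseline: T2D by FPG but untreated
    newly = np.zeros(n, dtype=bool)
    candidates = np.flatnonzero(t2d & ~meds)
    k = min(cfg.newly_diagnosed_count, len(candidates))
    if k > 0:
        newly[rng.choice(candidates, size=k, replace=False)] = True
    participants["newly_diagnosed_t2d"] = newly

    # glycaemic traits driven by the same liability
    lz = (liability - liability.mean()) / liability.std(ddof=1)
    participants["homa_ir"] = np.exp(
        np.log(2.0) + 0.45 * lz + 0.4 * rng.normal(size=n)
    )
    participants["hba1c"] = 5.7 + 0.55 * lz + 0.35 * rng.normal(size=n)

    # measure panel
    reg = build_registry(cfg, registry)
    matrix = _draw_measure_panel(cfg, rng, reg, mediator_z)
    matrix.index = participants.index
    matrix = _inject_missing_and_zeros(cfg, rng, matrix, reg)

    participants["metabolites_measured"] = True

    # covariate missingness
    for col, rate in cfg.covariate_missing.items():
        if rate <= 0 or col not in participants.columns:
            continue
        miss = rng.random(n) < rate
        participants.loc[miss, col] = np.nan

    # planted exclusions
    participants, matrix, planted = plant_exclusion_conditions(
        participants, matrix, cfg.exclusion_counts, rng
    )
    participants.loc[planted["no_metabolites"], "metabolites_measured"] = False

    truth = SimTruth(
        mediator_names=mediator_names,
        a=list(map(float, a)),
        b=list(map(float, b)),
        c_direct=float(cfg.c_direct),
        proportion_mediated=list(
            map(float, planted_proportions(a, b, cfg.c_direct))
        ),
        exclusion_counts=tuple(cfg.exclusion_counts),
        incidence_rr=float(cfg.incidence_rr),
        rr_measure=cfg.rr_measure,
        gms_thresholds=tuple(map(float, thresholds)),
    )
    return participants, matrix, truth


def generate_followup(
    cohort: pd.DataFrame,
    measure_z: pd.Series,
    years: int = 7,
    incidence_rr: float = 1.0,
    base_rates: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Yearly incident-T2D follow-up for NGM / prediabetes participants.

    The per-year hazard is ``base_rate[stratum] · RR**z`` with ``z`` the
    measure in SD units; once incident, always incident; participants with
    T2D at baseline are excluded from the risk set.  Follow-up duration is a
    clipped normal (mean 5.83, SD 0.91 years) rounded to whole years, capped
    at ``years``.
    """
    if years < 1:
        raise ConfigError("years must be >= 1")
    if base_rates is None:
        base_rates = DEFAULT_BASE_RATES
    rng = np.random.default_rng(seed)
    at_risk = cohort[cohort["gms"] < 2]
    z = measure_z.reindex(at_risk.index).to_numpy(dtype=float)
    z = np.where(np.isnan(z), 0.0, z)
    gms = at_risk["gms"].to_numpy()
    n = len(at_risk)
    duration = np.clip(
        np.round(rng.normal(5.83, 0.91, n)).astype(int), 1, years
    )
    base = np.where(gms == 1, base_rates[1], base_rates[0])
    hazard = np.clip(base * incidence_rr ** z, 0.0, 1.0)

    rows = []
    incident = np.zeros(n, dtype=bool)
    for year in range(1, years + 1):
        active = duration >= year
        new_events = active & ~incident & (rng.random(n) < hazard)
        incident |= new_events
        for i in np.flatnonzero(active):
            rows.append((at_risk["id"].iloc[i], int(gms[i]), year,
                         int(incident[i])))
    return pd.DataFrame(rows, columns=["id", "baseline_gms", "year",
                                       "incident"])


def write_cohort(
    outdir,
    participants: pd.DataFrame,
    matrix: pd.DataFrame,
    truth: SimTruth,
    registry: MeasureRegistry | None = None,
) -> None:
    """Write the standard pipeline inputs as delimited text + JSON sidecar."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    participants.to_csv(outdir / "participants.tsv", sep="\t", index=False)
    matrix.to_csv(outdir / "metabolites.tsv", sep="\t", index=False)
    truth.to_json(outdir / "sim_truth.json")
    if registry is not None:
        registry.table.to_csv(outdir / "registry.tsv", sep="\t", index=False)
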