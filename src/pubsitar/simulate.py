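"""Synthetic longitudinal puberty cohort generator.

Emulates the observed-data design of a UK birth-cohort puberty study:
nine clinic visits (~7-18 y) measuring height, weight and bone mineral
content (BMC at the five DXA clinics only), and nine puberty questionnaires
(~8-17 y) reporting Tanner stages (pubic hair; breast in females; genitalia
in males), voice breaking (3-point, males), axillary hair (2-point) and
menarche (females).

Every individual carries SITAR random effects per measure — size (alpha),
timing (beta), intensity (gamma) and post-growth slope (delta) — generated
around analytic mean curves, so the true effects are available as oracles
for every downstream estimator.  Cross-measure coupling of timing is a
one-factor model: beta_m = timing_sd_m * (lambda_m * eta + sqrt(1-lambda_m^2) * eps_m)
with a single standard-normal latent factor eta per individual; the default
loading lambda = sqrt(cross_measure_timing_correlation) gives equicorrelated
measure timings.

The covariate table carries a simulated standardized puberty GRS (correlated
with eta at `grs_timing_correlation`), an adiposity GRS, fat/lean mass index
z-scores at ~10 y, and maternal/childhood confounders.  The structural part
is a small linear SEM: maternal BMI (confounder) -> fat mass index -> latent
timing, with known path coefficients, so adjusted/unadjusted regression
behaviour has closed-form expectations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .curves import (LatentStageCurve, SigmoidGrowthCurve, SplineGrowthCurve,
                     sitar_generative_curve)
from .exceptions import ConfigError

__all__ = [
    "MeasureConfig",
    "SimConfig",
    "TrueEffects",
    "Cohort",
    "default_measures",
    "spline_growth_curve",
    "simulate_cohort",
    "discretize_to_stages",
]

CLINIC_AGES = (7.5, 8.5, 9.9, 10.7, 11.8, 12.8, 13.8, 15.4, 17.8)
QUESTIONNAIRE_AGES = (8.1, 9.7, 10.6, 11.7, 12.5, 13.1, 14.7, 16.0, 17.0)

# ordinal scale sizes by measure kind
STAGE_LEVELS = {5: 3.0, 3: 2.0, 2: 1.5}  # landmark level by number of categories


@dataclass(frozen=True)
class MeasureConfig:
    """Generative settings for one measure.

    kind: 'growth' (continuous clinic outcome), 'stage' (ordinal
    questionnaire outcome) or 'event' (menarche).
    """

    name: str
    kind: str
    schedule: str  # 'clinic' or 'questionnaire'
    sexes: tuple
    curve_by_sex: dict = field(default_factory=dict)
    mean_age_by_sex: dict = field(default_factory=dict)  # events only
    timing_sd: float = 1.0
    size_sd: float = 0.0
    intensity_sd: float = 0.15
    postgrowth_sd: float = 0.0
    residual_sd: float = 0.5
    visit_indices: tuple | None = None  # subset of schedule visits, None = all
    loading: float | None = None  # override for the one-factor loading

    def __post_init__(self):
        for fld in ("timing_sd", "size_sd", "intensity_sd", "postgrowth_sd",
                    "residual_sd"):
            if getattr(self, fld) < 0:
                raise ConfigError(f"measure '{self.name}': {fld} must be >= 0")
        if self.kind not in ("growth", "stage", "event"):
            raise ConfigError(f"measure '{self.name}': unknown kind '{self.kind}'")
        if self.kind == "stage":
            for sex, curve in self.curve_by_sex.items():
                if not isinstance(curve, LatentStageCurve):
                    raise ConfigError(
                        f"measure '{self.name}': stage measures need a "
                        f"LatentStageCurve (sex {sex})")
        if self.loading is not None and not 0.0 <= self.loading <= 1.0:
            raise ConfigError(f"measure '{self.name}': loading must be in [0,1]")

    def landmark_level(self) -> float | None:
        if self.kind != "stage":
            return None
        any_curve = next(iter(self.curve_by_sex.values()))
        return STAGE_LEVELS[any_curve.n_stages]


def spline_growth_curve(sigmoid: SigmoidGrowthCurve, schedule_ages,
                        n_knots: int = 4,
                        jitter_sd: float = 2.0 / 12.0) -> SplineGrowthCurve:
    """Project a sigmoid distance curve onto a natural-spline basis with
    knots placed by the same rule a fit applies to such data: boundary
    knots at the population age range (nominal schedule extended by the
    visit-age window) and `n_knots` internal knots at equally spaced
    quantiles of the population age distribution (every visit equally
    attended, exact ages uniform in the visit window).  The generator curve
    therefore lies in the fitted model family."""
    ages = np.asarray(schedule_ages, float)
    probs = np.arange(1, n_knots + 1) / (n_knots + 1)
    hw = math.sqrt(3.0) * jitter_sd
    base = np.repeat(ages, 399)
    if jitter_sd > 0:
        offsets = (2.0 * (np.arange(399) + 0.5) / 399 - 1.0) * hw
        base = base + np.tile(offsets, ages.size)
    internal = np.quantile(base, probs)
    knots = np.concatenate([[ages[0] - hw], internal, [ages[-1] + hw]])
    if np.any(np.diff(knots) <= 0):
        raise ConfigError("schedule too short for the requested knot count")
    # project over a window wide enough to cover timing-shifted ages
    return SplineGrowthCurve.from_function(sigmoid.value, knots,
                                           lo=ages[0] - 2.0, hi=ages[-1] + 2.0)


def default_measures() -> dict:
    """Default per-measure generative settings.

    Mean landmark ages follow the sex-specific ordering reported for this
    study design (earliest: breast ~11.5 y in females, pubic hair ~12.6 y in
    males; latest: menarche ~12.7 y and voice breaking ~14.2 y).  Height uses
    three random effects (timing SD 1.0 y, intensity SD 0.15, size SD 3 cm,
    residual 0.8 cm); weight and BMC add a post-growth slope effect.

    Growth mean curves are realistic sigmoids (childhood growth switching
    off in late adolescence plus a logistic spurt) projected onto a
    natural-spline basis, i.e. exactly the curve family SITAR assumes.
    """
    ca = np.asarray(CLINIC_AGES)
    dxa = ca[[2, 4, 6, 7, 8]]
    m = {}
    m["height"] = MeasureConfig(
        name="height", kind="growth", schedule="clinic", sexes=("F", "M"),
        curve_by_sex={
            "F": spline_growth_curve(
                SigmoidGrowthCurve(122.0, 5.2, 13.6, 1.0, 14.0, 11.8, 0.9), ca),
            "M": spline_growth_curve(
                SigmoidGrowthCurve(124.0, 5.3, 15.3, 1.0, 17.0, 13.5, 1.0), ca),
        },
        timing_sd=1.0, size_sd=3.0, intensity_sd=0.15, postgrowth_sd=0.0,
        residual_sd=0.8)
    m["weight"] = MeasureConfig(
        name="weight", kind="growth", schedule="clinic", sexes=("F", "M"),
        curve_by_sex={
            "F": spline_growth_curve(
                SigmoidGrowthCurve(25.0, 2.3, 14.5, 1.2, 15.0, 12.1, 1.1), ca),
            "M": spline_growth_curve(
                SigmoidGrowthCurve(26.0, 2.5, 16.0, 1.2, 21.0, 13.8, 1.1), ca),
        },
        timing_sd=1.1, size_sd=2.5, intensity_sd=0.2, postgrowth_sd=0.4,
        residual_sd=1.0)
    m["bmc"] = MeasureConfig(
        name="bmc", kind="growth", schedule="clinic", sexes=("F", "M"),
        curve_by_sex={
            "F": spline_growth_curve(
                SigmoidGrowthCurve(900.0, 90.0, 15.0, 1.2, 750.0, 12.4, 1.0),
                dxa, n_knots=3),
            "M": spline_growth_curve(
                SigmoidGrowthCurve(950.0, 95.0, 16.0, 1.2, 950.0, 13.2, 1.0),
                dxa, n_knots=3),
        },
        timing_sd=0.9, size_sd=120.0, intensity_sd=0.18, postgrowth_sd=20.0,
        residual_sd=50.0,
        visit_indices=(2, 4, 6, 7, 8))  # the five DXA clinics, ~9.9-17.8 y
    m["pubic_hair"] = MeasureConfig(
        name="pubic_hair", kind="stage", schedule="questionnaire",
        sexes=("F", "M"),
        curve_by_sex={"F": LatentStageCurve(5, 11.9, 0.7),
                      "M": LatentStageCurve(5, 12.6, 0.7)},
        timing_sd=1.0, intensity_sd=0.15, residual_sd=0.35)
    m["breast"] = MeasureConfig(
        name="breast", kind="stage", schedule="questionnaire", sexes=("F",),
        curve_by_sex={"F": LatentStageCurve(5, 11.5, 0.7)},
        timing_sd=1.1, intensity_sd=0.15, residual_sd=0.35)
    m["genitalia"] = MeasureConfig(
        name="genitalia", kind="stage", schedule="questionnaire", sexes=("M",),
        curve_by_sex={"M": LatentStageCurve(5, 12.9, 0.7)},
        timing_sd=1.2, intensity_sd=0.15, residual_sd=0.35)
    m["axillary_hair"] = MeasureConfig(
        name="axillary_hair", kind="stage", schedule="questionnaire",
        sexes=("F", "M"),
        curve_by_sex={"F": LatentStageCurve(2, 12.2, 0.5),
                      "M": LatentStageCurve(2, 13.6, 0.5)},
        timing_sd=1.0, intensity_sd=0.15, residual_sd=0.25,
        visit_indices=(2, 3, 4, 5, 6, 7, 8))  # collected from ~10 y onward
    m["voice"] = MeasureConfig(
        name="voice", kind="stage", schedule="questionnaire", sexes=("M",),
        curve_by_sex={"M": LatentStageCurve(3, 14.2, 0.6)},
        timing_sd=1.0, intensity_sd=0.15, residual_sd=0.30,
        visit_indices=(1, 2, 3, 4, 5, 6, 7, 8))  # not asked at Q1
    m["menarche"] = MeasureConfig(
        name="menarche", kind="event", schedule="questionnaire", sexes=("F",),
        mean_age_by_sex={"F": 12.7}, timing_sd=1.2)
    return m


@dataclass(frozen=True)
class SimConfig:
    """Cohort simulation settings; defaults emulate the study design."""

    n_per_sex: int = 500
    clinic_ages: tuple = CLINIC_AGES
    questionnaire_ages: tuple = QUESTIONNAIRE_AGES
    measures: dict = field(default_factory=default_measures)
    cross_measure_timing_correlation: float = 0.5
    age_jitter_sd: float = 2.0 / 12.0  # ~2 months around nominal visit ages
    missingness_clinic: float = 0.10
    missingness_questionnaire: float = 0.20
    inconsistency_rate: float = 0.05
    menarche_recall_sd: float = 0.25  # y
    grs_timing_correlation: float = 0.25
    grs_bmi_fmi_correlation: float = 0.30
    fmi_effect: float = -0.35  # effect of FMI z on latent timing, SD units
    confounder_effect: float = -0.20  # maternal BMI z -> latent timing, SD units
    fmi_confounder_corr: float = 0.40  # maternal BMI z -> FMI z path
    seed: int = 0

    def __post_init__(self):
        if self.n_per_sex < 1:
            raise ConfigError("n_per_sex must be >= 1")
        ca = np.asarray(self.clinic_ages, float)
        if ca.ndim != 1 or not np.all(np.diff(ca) > 0):
            raise ConfigError("clinic_ages must be strictly increasing")
        qa = np.asarray(self.questionnaire_ages, float)
        if qa.ndim != 1 or not np.all(np.diff(qa) > 0):
            raise ConfigError("questionnaire_ages must be strictly increasing")
        for fld in ("cross_measure_timing_correlation", "grs_timing_correlation",
                    "grs_bmi_fmi_correlation", "fmi_confounder_corr"):
            if not -1.0 <= getattr(self, fld) <= 1.0:
                raise ConfigError(f"{fld} must be in [-1, 1]")
        if self.cross_measure_timing_correlation < 0:
            raise ConfigError("cross_measure_timing_correlation must be in [0, 1]")
        for fld in ("age_jitter_sd", "menarche_recall_sd"):
            if getattr(self, fld) < 0:
                raise ConfigError(f"{fld} must be >= 0")
        for fld in ("missingness_clinic", "missingness_questionnaire",
                    "inconsistency_rate"):
            if not 0.0 <= getattr(self, fld) <= 1.0:
                raise ConfigError(f"{fld} must be in [0, 1]")
        # structural timing model must leave non-negative residual variance
        qf, qc, qg = self.fmi_effect, self.confounder_effect, self.grs_timing_correlation
        explained = qg**2 + qf**2 + qc**2 + 2 * qf * qc * self.fmi_confounder_corr
        if explained >= 1.0:
            raise ConfigError(
                "grs_timing_correlation/fmi_effect/confounder_effect explain "
                ">= 100% of latent timing variance")

    def with_measures(self, names) -> "SimConfig":
        """Restrict the simulation to a subset of measures."""
        missing = set(names) - set(self.measures)
        if missing:
            raise ConfigError(f"unknown measures: {sorted(missing)}")
        return replace(self, measures={k: self.measures[k] for k in names})

    def loading(self, measure: str) -> float:
        mc = self.measures[measure]
        if mc.loading is not None:
            return mc.loading
        return math.sqrt(self.cross_measure_timing_correlation)

    def true_landmark_age(self, measure: str, sex: str) -> float:
        """Analytic population landmark age for a measure/sex (oracle)."""
        mc = self.measures[measure]
        if mc.kind == "growth":
            return mc.curve_by_sex[sex].peak_velocity_age()
        if mc.kind == "stage":
            curve = mc.curve_by_sex[sex]
            return curve.crossing(STAGE_LEVELS[curve.n_stages])
        return mc.mean_age_by_sex[sex]


@dataclass
class TrueEffects:
    """Ground-truth latent quantities from one simulated cohort.

    per_measure: one row per (id, measure) with alpha/beta/gamma/delta.
    per_individual: one row per id with the latent timing factor eta,
    structural covariate values and (females) the true menarche age.
    """

    per_measure: pd.DataFrame
    per_individual: pd.DataFrame

    def beta_wide(self) -> pd.DataFrame:
        """Timing effects as an id x measure table (years)."""
        return self.per_measure.pivot(index="id", columns="measure",
                                      values="beta")


@dataclass
class Cohort:
    """A simulated cohort: long measurement table + truths + covariates."""

    measurements: pd.DataFrame  # id, sex, age_months, measure, value, occasion
    true_effects: TrueEffects
    covariates: pd.DataFrame
    config: SimConfig

    def measurement_series(self, measure: str) -> pd.DataFrame:
        out = self.measurements[self.measurements["measure"] == measure]
        return out.reset_index(drop=True)


def discretize_to_stages(latent_values, thresholds, inconsistency_rate=0.0,
                         rng=None):
    """Threshold latent development values into ordinal stages 1..K.

    thresholds: K-1 strictly increasing stage boundaries.  With probability
    `inconsistency_rate` a report regresses by one stage (floored at 1),
    emulating inconsistent questionnaire responses.
    """
    thresholds = np.asarray(thresholds, float)
    if thresholds.ndim != 1 or thresholds.size < 1:
        raise ConfigError("thresholds must be a non-empty 1-d sequence")
    if np.any(np.diff(thresholds) <= 0):
        raise ConfigError("thresholds must be strictly increasing")
    latent = np.asarray(latent_values, float)
    stage = 1 + np.searchsorted(thresholds, latent, side="left")
    stage = stage.astype(int)
    if inconsistency_rate > 0:
        if rng is None:
            raise ConfigError("rng required when inconsistency_rate > 0")
        flip = rng.random(stage.shape) < inconsistency_rate
        stage = np.where(flip & (stage > 1), stage - 1, stage)
    return stage


def _draw_effects(rng, config: SimConfig, ids, sexes):
    """Latent factor, structural covariates and per-measure random effects."""
    n = len(ids)
    qg = config.grs_timing_correlation
    qf = config.fmi_effect
    qc = config.confounder_effect
    a_cf = config.fmi_confounder_corr
    a_gb = config.grs_bmi_fmi_correlation

    g_pub = rng.standard_normal(n)  # puberty GRS (pre-standardization)
    g_bmi = rng.standard_normal(n)
    conf = rng.standard_normal(n)  # maternal BMI z (structural confounder)
    resid_var = 1.0 - a_cf**2 - a_gb**2
    fmi = a_cf * conf + a_gb * g_bmi + math.sqrt(resid_var) * rng.standard_normal(n)
    explained = qg**2 + qf**2 + qc**2 + 2 * qf * qc * a_cf
    eta = (qg * g_pub + qf * fmi + qc * conf
           + math.sqrt(1.0 - explained) * rng.standard_normal(n))

    lmi = 0.45 * fmi + math.sqrt(1 - 0.45**2) * rng.standard_normal(n)

    per_ind = pd.DataFrame({
        "id": ids, "sex": sexes, "eta": eta,
        "grs_puberty_raw": g_pub, "grs_bmi_raw": g_bmi,
        "maternal_bmi_z": conf, "fmi_z": fmi, "lmi_z": lmi,
    })

    rows = []
    for name, mc in config.measures.items():
        lam = config.loading(name)
        eps = rng.standard_normal(n)
        beta = mc.timing_sd * (lam * eta + math.sqrt(1 - lam**2) * eps)
        alpha = mc.size_sd * rng.standard_normal(n) if mc.size_sd > 0 else np.zeros(n)
        gamma = (mc.intensity_sd * rng.standard_normal(n)
                 if mc.kind != "event" and mc.intensity_sd > 0 else np.zeros(n))
        delta = (mc.postgrowth_sd * rng.standard_normal(n)
                 if mc.postgrowth_sd > 0 else np.zeros(n))
        rows.append(pd.DataFrame({
            "id": ids, "sex": sexes, "measure": name,
            "alpha": alpha, "beta": beta, "gamma": gamma, "delta": delta,
        }))
    per_measure = pd.concat(rows, ignore_index=True)
    return per_ind, per_measure


def simulate_cohort(config: SimConfig, seed: int | None = None) -> Cohort:
    """Simulate a full cohort; reproducible given (config, seed).

    seed defaults to config.seed.  Returns a :class:`Cohort` whose
    measurement table is long-format (id, sex, age_months, measure, value,
    occasion) with age recorded in months.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_per_sex
    ids = ([f"F{i:05d}" for i in range(1, n + 1)]
           + [f"M{i:05d}" for i in range(1, n + 1)])
    sexes = ["F"] * n + ["M"] * n
    per_ind, per_measure = _draw_effects(rng, config, ids, sexes)

    schedules = {"clinic": np.asarray(config.clinic_ages, float),
                 "questionnaire": np.asarray(config.questionnaire_ages, float)}
    miss = {"clinic": config.missingness_clinic,
            "questionnaire": config.missingness_questionnaire}
    n_all = len(ids)

    # visit-level attendance and exact ages, shared by all measures on the
    # same schedule (one clinic visit yields height, weight and BMC together)
    visit_age = {}
    attended = {}
    # exact ages uniform in a bounded window around each nominal visit age
    # (SD = age_jitter_sd); bounded support keeps the population age range
    # finite, so quantile- and boundary-knot placement has a stable target
    hw = math.sqrt(3.0) * config.age_jitter_sd
    for sched, nominal in schedules.items():
        jitter = rng.uniform(-hw, hw, size=(n_all, nominal.size))
        visit_age[sched] = nominal[None, :] + jitter
        attended[sched] = rng.random((n_all, nominal.size)) >= miss[sched]

    sex_arr = np.asarray(sexes)
    eff = {(r.measure): None for r in per_measure.itertuples()}  # noqa: F841
    eff_by_measure = {
        name: grp.set_index("id").loc[ids]
        for name, grp in per_measure.groupby("measure")
    }

    frames = []
    for name, mc in config.measures.items():
        e = eff_by_measure[name]
        ages = visit_age[mc.schedule]
        att = attended[mc.schedule]
        vis = (np.arange(ages.shape[1]) if mc.visit_indices is None
               else np.asarray(mc.visit_indices, int))
        sex_mask = np.isin(sex_arr, mc.sexes)

        if mc.kind == "event":
            frames.append(_simulate_event(rng, config, mc, e, ids, sex_arr,
                                          ages, att, vis, sex_mask))
            continue

        alpha = e["alpha"].to_numpy()[:, None]
        beta = e["beta"].to_numpy()[:, None]
        gamma = e["gamma"].to_numpy()[:, None]
        delta = e["delta"].to_numpy()[:, None]
        a = ages[:, vis]
        # intensity stretches the age scale around the centre of the
        # measure's observation window (the canonical SITAR rotation)
        center = float(schedules[mc.schedule][vis].mean())
        x = np.exp(gamma) * (a - center - beta) + center

        for sex in mc.sexes:
            curve = mc.curve_by_sex[sex]
            rows_mask = (sex_arr == sex)
            xm = x[rows_mask]
            am = a[rows_mask]
            if mc.kind == "growth":
                upper = schedules[mc.schedule][-1] - 2.0  # adult-slope onset
                val = (alpha[rows_mask] + curve.value(xm)
                       + delta[rows_mask] * np.maximum(am - upper, 0.0))
                val = val + rng.normal(0.0, mc.residual_sd, size=val.shape)
            else:
                latent = curve.value(xm)
                latent = latent + rng.normal(0.0, mc.residual_sd, size=latent.shape)
                val = discretize_to_stages(latent, curve.thresholds,
                                           config.inconsistency_rate, rng)
                val = val.astype(float)
            keep = att[rows_mask][:, vis]
            idx_ind, idx_vis = np.nonzero(keep)
            id_sub = np.asarray(ids)[rows_mask]
            frames.append(pd.DataFrame({
                "id": id_sub[idx_ind],
                "sex": sex,
                "age_months": am[idx_ind, idx_vis] * 12.0,
                "measure": name,
                "value": val[idx_ind, idx_vis],
                "occasion": vis[idx_vis],
            }))

    measurements = pd.concat(frames, ignore_index=True)
    measurements = measurements.sort_values(
        ["measure", "id", "occasion"]).reset_index(drop=True)

    cov = per_ind.copy()
    for raw, out in (("grs_puberty_raw", "grs_puberty"),
                     ("grs_bmi_raw", "grs_bmi")):
        v = cov[raw].to_numpy()
        cov[out] = (v - v.mean()) / v.std(ddof=1)
    # plausible but structurally inert confounders round out the table
    n_all = len(ids)
    cov["fmi_age_y"] = 9.9 + rng.normal(0.0, 0.15, n_all)
    cov["maternal_age"] = np.round(28.0 + 5.0 * rng.standard_normal(n_all), 1)
    cov["maternal_education"] = rng.integers(1, 5, n_all)
    cov["parity"] = rng.binomial(3, 0.35, n_all)
    cov["maternal_smoking"] = rng.binomial(1, 0.2, n_all).astype(int)
    cov["child_energy_kj"] = np.round(rng.normal(6500.0, 900.0, n_all), 0)
    cov = cov.drop(columns=["grs_puberty_raw", "grs_bmi_raw"])

    # true menarche age for females (event measure present or not)
    if "menarche" in config.measures:
        mc = config.measures["menarche"]
        e = eff_by_measure["menarche"]
        men_age = np.where(sex_arr == "F",
                           mc.mean_age_by_sex.get("F", np.nan)
                           + e["beta"].to_numpy(), np.nan)
        per_ind = per_ind.assign(menarche_age=men_age)

    truths = TrueEffects(per_measure=per_measure, per_individual=per_ind)
    return Cohort(measurements=measurements, true_effects=truths,
                  covariates=cov, config=config)


def _simulate_event(rng, config, mc, e, ids, sex_arr, ages, att, vis, sex_mask):
    """Menarche-style event: reported (with recall noise) at every returned
    questionnaire on or after occurrence; value = reported onset age in
    months."""
    mean_age = mc.mean_age_by_sex.get("F", 12.7)
    beta = e["beta"].to_numpy()
    onset = mean_age + beta  # true event age, y
    rows = {"id": [], "sex": [], "age_months": [], "measure": [],
            "value": [], "occasion": []}
    id_arr = np.asarray(ids)
    for i in np.nonzero(sex_mask)[0]:
        for j in vis:
            if not att[i, j]:
                continue
            visit_age = ages[i, j]
            if visit_age < onset[i]:
                continue
            reported = onset[i] + rng.normal(0.0, config.menarche_recall_sd)
            rows["id"].append(id_arr[i])
            rows["sex"].append(sex_arr[i])
            rows["age_months"].append(visit_age * 12.0)
            rows["measure"].append(mc.name)
            rows["value"].append(reported * 12.0)  # reported onset age, months
            rows["occasion"].append(int(j))
    return pd.DataFrame(rows)
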