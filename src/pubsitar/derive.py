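"""Derivation of indicator-based pubertal ages.

Nine pubertal-timing measures are derived per cohort: ages at peak height,
weight and BMC velocity (APHV/APWV/APBMCV) from three- or four-effect SITAR
fits; ages in Tanner stage 3 of pubic hair, breast (females) and genitalia
(males); age at axillary hair appearance and age at voice breaking from
reduced two-effect (timing + intensity) fits of the ordinal scores treated
as continuous; and age at menarche taken directly as the first reported
onset age.  For every modelled measure the per-individual pubertal age is
the population landmark age (peak velocity, or the mean curve's crossing of
the landmark level) plus the individual's timing BLUP.

Landmark levels: Tanner scales cross 3.0 (entry into stage 3); voice
breaking (3-point) crosses 2.0 and axillary hair (2-point) crosses 1.5 —
the natural event boundary at the midpoint of each scale.  Both are
configurable per measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError, FitError, LandmarkError
from .sitar import (SitarFit, SitarSpec, age_at_level, age_at_peak_velocity,
                    fit_sitar, individual_pubertal_age, remove_outliers,
                    select_model)

__all__ = [
    "MeasureModel", "DEFAULT_MEASURE_MODELS", "DERIVED_NAME", "DeriveResult",
    "derive_menarche_age", "clean_voice_series", "derive_all_measures",
    "summarize_timing", "apv_outlier_sensitivity",
]


@dataclass(frozen=True)
class MeasureModel:
    """How one measure is modelled and which landmark defines its age."""

    random_effects: tuple
    n_knots: int
    landmark: str  # 'peak_velocity' or 'level'
    level: float | None = None
    clean_inconsistent: bool = False
    sexes: tuple = ("F", "M")


DEFAULT_MEASURE_MODELS = {
    "height": MeasureModel(("size", "timing", "intensity"), 4, "peak_velocity"),
    "weight": MeasureModel(("size", "timing", "intensity", "postgrowth"), 4,
                           "peak_velocity"),
    # only five DXA clinics observe BMC; 3 internal knots is the most the
    # five-visit schedule supports stably
    "bmc": MeasureModel(("size", "timing", "intensity", "postgrowth"), 3,
                        "peak_velocity"),
    "pubic_hair": MeasureModel(("timing", "intensity"), 4, "level", 3.0),
    "breast": MeasureModel(("timing", "intensity"), 4, "level", 3.0,
                           sexes=("F",)),
    "genitalia": MeasureModel(("timing", "intensity"), 4, "level", 3.0,
                              sexes=("M",)),
    "axillary_hair": MeasureModel(("timing", "intensity"), 4, "level", 1.5),
    "voice": MeasureModel(("timing", "intensity"), 4, "level", 2.0,
                          clean_inconsistent=True, sexes=("M",)),
}

# derived-age column names in the output table
DERIVED_NAME = {
    "height": "aphv", "weight": "apwv", "bmc": "apbmcv",
    "pubic_hair": "pubic_hair_3", "breast": "breast_3",
    "genitalia": "genitalia_3", "axillary_hair": "axillary_hair",
    "voice": "voice_breaking", "menarche": "menarche",
}


def derive_menarche_age(data: pd.DataFrame) -> pd.Series:
    """Age at menarche = first reported onset age, in years.

    `data` holds 'menarche' rows of the long table: value is the reported
    onset age in months; the earliest questionnaire report wins when
    repeated reports disagree.  Individuals never reporting onset are
    absent from the result (missing).
    """
    df = data
    if "measure" in df.columns:
        df = df[df["measure"] == "menarche"]
    if df.empty:
        return pd.Series(dtype=float, name="menarche")
    sort_cols = [c for c in ("id", "occasion", "age_months") if c in df.columns]
    first = (df.dropna(subset=["value"])
               .sort_values(sort_cols)
               .groupby("id", sort=True)
               .first())
    out = first["value"] / 12.0
    out.name = "menarche"
    return out


def clean_voice_series(data: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop voice-breaking reports that regress below the individual's
    running maximum (inconsistent responses), returning (cleaned, n_removed).
    Other measures should be passed through unfiltered."""
    df = data.copy()
    sort_cols = [c for c in ("id", "age_months", "occasion") if c in df.columns]
    df = df.sort_values(sort_cols, kind="stable")
    prev_max = (df.groupby("id")["value"]
                  .transform(lambda s: s.cummax().shift(1)))
    drop = df["value"] < prev_max
    return df[~drop].reset_index(drop=True), int(drop.sum())


@dataclass
class DeriveResult:
    """Derived pubertal ages plus the fitted models behind them."""

    table: pd.DataFrame  # id, sex, one column per derived measure (years)
    fits: dict = field(default_factory=dict)  # (measure, sex) -> SitarFit
    landmarks: dict = field(default_factory=dict)  # (measure, sex) -> age (y)
    skipped: list = field(default_factory=list)  # (measure, sex, reason)


def _landmark(fit: SitarFit, model: MeasureModel) -> float:
    if model.landmark == "peak_velocity":
        return age_at_peak_velocity(fit)
    return age_at_level(fit, model.level)


def derive_all_measures(measurements: pd.DataFrame,
                        models: dict | None = None,
                        select_knots: bool = False,
                        knot_candidates=(2, 3, 4, 5)) -> DeriveResult:
    """Fit every measure per sex and assemble the pubertal-age table.

    `measurements` is the long table (id, sex, age_months, measure, value).
    Models are fitted separately in males and females.  Measures whose fit
    or landmark fails are skipped with a warning and recorded in
    `skipped`.  With select_knots=True the knot count is chosen by BIC over
    `knot_candidates` instead of the per-measure default.
    """
    models = dict(DEFAULT_MEASURE_MODELS, **(models or {}))
    present = set(measurements["measure"].unique())
    result = DeriveResult(table=pd.DataFrame())
    pieces = []

    for measure, model in models.items():
        if measure not in present:
            continue
        data_m = measurements[measurements["measure"] == measure]
        if model.clean_inconsistent:
            data_m, _ = clean_voice_series(data_m)
        for sex in model.sexes:
            data_ms = data_m[data_m["sex"] == sex]
            if data_ms.empty:
                continue
            spec = SitarSpec(outcome=measure,
                             random_effects=model.random_effects,
                             n_knots=model.n_knots)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    if select_knots:
                        fit, _ = select_model(data_ms, spec, knot_candidates)
                    else:
                        fit = fit_sitar(data_ms, spec)
                landmark = _landmark(fit, model)
            except (FitError, DataError, LandmarkError) as exc:
                warnings.warn(f"{measure} ({sex}): skipped — {exc}",
                              RuntimeWarning)
                result.skipped.append((measure, sex, str(exc)))
                continue
            result.fits[(measure, sex)] = fit
            result.landmarks[(measure, sex)] = landmark
            ages = individual_pubertal_age(fit, landmark)
            pieces.append(pd.DataFrame({
                "id": ages.index, "sex": sex,
                "measure": DERIVED_NAME[measure],
                "age_y": ages.to_numpy(),
            }))

    if "menarche" in present:
        men = derive_menarche_age(measurements)
        if len(men):
            sex_of = (measurements[["id", "sex"]]
                      .drop_duplicates().set_index("id")["sex"])
            pieces.append(pd.DataFrame({
                "id": men.index, "sex": sex_of.reindex(men.index).to_numpy(),
                "measure": "menarche", "age_y": men.to_numpy(),
            }))

    if not pieces:
        raise DataError("no measure could be derived from the input table")
    long = pd.concat(pieces, ignore_index=True)
    table = (long.pivot_table(index=["id", "sex"], columns="measure",
                              values="age_y", aggfunc="first")
                 .reset_index())
    table.columns.name = None
    result.table = table
    return result


def summarize_timing(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sex, per-measure timing summary and chronological sequence.

    Returns one row per (sex, measure): n, mean and SD of the derived age
    (years), and — among individuals of that sex with complete data on all
    of the sex's measures — the percentage for whom the measure is
    chronologically first and last (ties split equally).
    """
    meta = {"id", "sex"}
    rows = []
    for sex, sub in table.groupby("sex"):
        measures = [c for c in table.columns
                    if c not in meta and sub[c].notna().any()]
        complete = sub.dropna(subset=measures)
        vals = complete[measures].to_numpy(float)
        first_w = np.zeros(len(measures))
        last_w = np.zeros(len(measures))
        for row in vals:
            lo, hi = row.min(), row.max()
            fm = row == lo
            lm = row == hi
            first_w += fm / fm.sum()
            last_w += lm / lm.sum()
        denom = max(len(complete), 1)
        for j, m in enumerate(measures):
            col = sub[m].dropna()
            if col.empty:
                continue
            rows.append({
                "sex": sex, "measure": m, "n": int(len(col)),
                "mean_y": float(col.mean()),
                "sd_y": float(col.std(ddof=1)) if len(col) > 1 else np.nan,
                "n_complete": int(len(complete)),
                "pct_first": 100.0 * first_w[j] / denom,
                "pct_last": 100.0 * last_w[j] / denom,
            })
    return pd.DataFrame(rows)


def apv_outlier_sensitivity(measurements: pd.DataFrame,
                            measures=("height", "weight", "bmc"),
                            threshold: float = 5.0,
                            models: dict | None = None) -> pd.DataFrame:
    """Sensitivity of peak-velocity ages to +/- threshold-SD outliers.

    Refits the anthropometric SITAR models after removing visit-level
    outliers and reports the peak-velocity age from both fits alongside
    the number and percentage of observations removed.
    """
    models = dict(DEFAULT_MEASURE_MODELS, **(models or {}))
    rows = []
    for measure in measures:
        model = models[measure]
        data_m = measurements[measurements["measure"] == measure]
        for sex in model.sexes:
            data_ms = data_m[data_m["sex"] == sex]
            if data_ms.empty:
                continue
            filtered, report = remove_outliers(data_ms, threshold)
            spec = SitarSpec(outcome=measure,
                             random_effects=model.random_effects,
                             n_knots=model.n_knots)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                apv_all = age_at_peak_velocity(fit_sitar(data_ms, spec))
                apv_filt = age_at_peak_velocity(fit_sitar(filtered, spec))
            rows.append({
                "measure": measure, "sex": sex,
                "apv_all_y": apv_all, "apv_filtered_y": apv_filt,
                "n_removed": report.n_removed,
                "pct_removed": report.pct_removed,
            })
    return pd.DataFrame(rows)
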