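"""End-to-end pipeline: simulate/read -> fit & derive -> summarize -> associate.

Writes every artifact as CSV/JSON in the output directory and a provenance
manifest (seed, config hash, package and dependency versions).  Stage
failures raise :class:`PipelineError` carrying the stage name; artifacts
written before the failure are left in place.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import pairwise_correlations, regress_adjusted, regress_univariable
from .derive import (apv_outlier_sensitivity, derive_all_measures,
                     summarize_timing)
from .exceptions import DataError, PipelineError, PubsitarError
from .io import (PipelineConfig, config_hash, read_measurements, save_fit,
                 write_measurements)
from .simulate import SimConfig, simulate_cohort

__all__ = ["run_pipeline"]


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, (PubsitarError,
                                                    ValueError, KeyError)):
                raise PipelineError(name, str(exc)) from exc
            return False
    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a dict of output paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {}

    with _stage("simulate"):
        if config.measurements_path is None:
            sim_cfg = SimConfig(**{**config.simulate, "seed": config.seed})
            cohort = simulate_cohort(sim_cfg)
            measurements = cohort.measurements
            covariates = cohort.covariates
            write_measurements(measurements, out / "measurements.csv")
            cohort.true_effects.per_measure.to_csv(
                out / "true_effects.csv", index=False)
            covariates.to_csv(out / "covariates.csv", index=False)
            artifacts["measurements"] = str(out / "measurements.csv")
            artifacts["true_effects"] = str(out / "true_effects.csv")
            artifacts["covariates"] = str(out / "covariates.csv")
        else:
            measurements = read_measurements(config.measurements_path)
            covariates = (pd.read_csv(config.covariates_path)
                          if config.covariates_path else None)

    with _stage("derive"):
        derived = derive_all_measures(measurements,
                                      models=config.measure_models or None,
                                      select_knots=config.select_knots)
        table = derived.table
        table.to_csv(out / "pubertal_ages.csv", index=False)
        artifacts["pubertal_ages"] = str(out / "pubertal_ages.csv")
        fits_dir = out / "fits"
        fits_dir.mkdir(exist_ok=True)
        for (measure, sex), fit in derived.fits.items():
            save_fit(fit, fits_dir / f"{measure}_{sex}.json")
        landmarks = pd.DataFrame(
            [{"measure": m, "sex": s, "landmark_age_y": a}
             for (m, s), a in derived.landmarks.items()])
        landmarks.to_csv(out / "landmarks.csv", index=False)
        artifacts["landmarks"] = str(out / "landmarks.csv")

    with _stage("summarize"):
        summary = summarize_timing(table)
        summary.to_csv(out / "timing_summary.csv", index=False)
        artifacts["timing_summary"] = str(out / "timing_summary.csv")
        for sex, sub in table.groupby("sex"):
            cols = [c for c in sub.columns if c not in ("id", "sex")
                    and sub[c].notna().any()]
            try:
                corr, n = pairwise_correlations(sub, cols)
            except DataError:
                continue
            corr.to_csv(out / f"correlations_{sex}.csv")
            artifacts[f"correlations_{sex}"] = str(
                out / f"correlations_{sex}.csv")

    if config.outlier_sensitivity:
        with _stage("outlier_sensitivity"):
            sens = apv_outlier_sensitivity(measurements)
            sens.to_csv(out / "outlier_sensitivity.csv", index=False)
            artifacts["outlier_sensitivity"] = str(
                out / "outlier_sensitivity.csv")

    if config.associate and covariates is not None:
        with _stage("associate"):
            rows = []
            merged = table.merge(covariates, on=[c for c in ("id", "sex")
                                                 if c in covariates.columns])
            measure_cols = [c for c in table.columns if c not in ("id", "sex")]
            for sex, sub in merged.groupby("sex"):
                for grs in config.grs_columns:
                    if grs not in sub.columns:
                        continue
                    for mcol in measure_cols:
                        pair = sub[[mcol, grs]].dropna()
                        if len(pair) < 3 or pair[grs].nunique() < 2:
                            continue
                        res = regress_univariable(
                            pair[mcol], pair[grs],
                            outcome_name=f"{mcol}_{sex}", exposure_name=grs)
                        rows.append(res.as_row())
            if rows:
                pd.DataFrame(rows).to_csv(out / "grs_associations.csv",
                                          index=False)
                artifacts["grs_associations"] = str(
                    out / "grs_associations.csv")

            rows = []
            confounders = [c for c in config.confounder_columns
                           if c in merged.columns]
            for sex, sub in merged.groupby("sex"):
                for exp in config.bodycomp_columns:
                    if exp not in sub.columns:
                        continue
                    for mcol in measure_cols:
                        cols = [mcol, exp] + confounders
                        sub2 = sub[cols].dropna()
                        if len(sub2) < len(cols) + 2:
                            continue
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            res = regress_adjusted(
                                sub2[mcol], sub2[exp], sub2[confounders],
                                outcome_name=f"{mcol}_{sex}",
                                exposure_name=exp)
                        rows.append(res.as_row())
            if rows:
                pd.DataFrame(rows).to_csv(
                    out / "bodycomp_associations.csv", index=False)
                artifacts["bodycomp_associations"] = str(
                    out / "bodycomp_associations.csv")

    manifest = {
        "package": "pubsitar",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "artifacts": sorted(artifacts),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    artifacts["manifest"] = str(out / "manifest.json")
    return artifacts
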