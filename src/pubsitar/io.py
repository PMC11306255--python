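"""Readers/writers for the package's table formats and fit artifacts.

All tables are plain CSV/TSV.  The long measurement table stores exact age
in months (column `age_months`); ages are converted to years for modelling
and reporting.  Fitted SITAR models serialize to self-describing JSON.
A minimal VCF reader extracts per-sample dosages from the DS FORMAT field
for GRS construction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, DataError
from .sitar import SitarFit, SitarSpec

__all__ = [
    "read_measurements", "write_measurements", "read_grs_weights",
    "read_dosages", "read_vcf_dosages", "save_fit", "load_fit",
    "PipelineConfig", "load_config", "config_hash",
]

MEASUREMENT_COLUMNS = ("id", "sex", "age_months", "measure", "value")


def read_measurements(path) -> pd.DataFrame:
    """Read and validate a long-format measurement CSV.

    Requires columns id, sex, age_months, measure, value (an `occasion`
    column is kept when present).  Ages must be numeric months; a table
    whose maximum age is below 25 is rejected as being in years.
    Duplicate (id, measure, occasion) rows are an error.
    """
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"measurement file missing column(s) {missing}")
    try:
        ages = pd.to_numeric(df["age_months"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise DataError(f"non-numeric age_months: {exc}") from None
    if np.nanmax(ages.to_numpy(float)) < 25:
        raise DataError(
            "age_months values all below 25 — ages look like years; "
            "supply exact age in months")
    key = ["id", "measure", "occasion"] if "occasion" in df.columns \
        else ["id", "measure", "age_months"]
    dup = df.duplicated(subset=key)
    if dup.any():
        raise DataError(f"{int(dup.sum())} duplicate (id, measure, occasion) "
                        "row(s) in measurement file")
    return df


def write_measurements(df: pd.DataFrame, path) -> None:
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"measurement table missing column(s) {missing}")
    df.to_csv(path, index=False)


def read_grs_weights(path) -> pd.DataFrame:
    """3-column TSV: snp, effect_allele, weight."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("snp", "effect_allele", "weight")
               if c not in df.columns]
    if missing:
        raise DataError(f"GRS weights file missing column(s) {missing}")
    return df


def read_dosages(path) -> pd.DataFrame:
    """Individuals x SNPs dosage matrix from CSV (first column = id) or,
    for .vcf files, from the DS FORMAT field."""
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        return read_vcf_dosages(path)
    df = pd.read_csv(path)
    return df.set_index(df.columns[0])


def read_vcf_dosages(path) -> pd.DataFrame:
    """Dosage matrix from a VCF with per-sample DS (dosage) FORMAT values."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise DataError("reading VCF dosages requires cyvcf2") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols = {}
    for variant in vcf:
        ds = variant.format("DS")
        if ds is None:
            raise DataError(f"variant {variant.ID} has no DS FORMAT field")
        cols[variant.ID] = np.asarray(ds, float).reshape(-1)
    return pd.DataFrame(cols, index=pd.Index(samples, name="id"))


# --------------------------------------------------------------------------
# fit serialization


def save_fit(fit: SitarFit, path) -> None:
    payload = {
        "spec": {
            "outcome": fit.spec.outcome,
            "random_effects": list(fit.spec.random_effects),
            "n_knots": fit.spec.n_knots,
            "max_iter": fit.spec.max_iter,
            "min_iter": fit.spec.min_iter,
            "tol": fit.spec.tol,
            "bic_n": fit.spec.bic_n,
        },
        "knots": fit.knots.tolist(),
        "coef": fit.coef.tolist(),
        "omega": fit.omega.tolist(),
        "sigma": fit.sigma,
        "loglik": fit.loglik,
        "bic": fit.bic,
        "converged": fit.converged,
        "n_individuals": fit.n_individuals,
        "n_observations": fit.n_observations,
        "adult_onset_age": fit.adult_onset_age,
        "age_center": fit.age_center,
        "n_iterations": fit.n_iterations,
        "blups": {
            "index": [str(i) for i in fit.blups.index],
            "columns": list(fit.blups.columns),
            "values": fit.blups.to_numpy().tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_fit(path) -> SitarFit:
    payload = json.loads(Path(path).read_text())
    spec = SitarSpec(**{**payload["spec"],
                        "random_effects": tuple(payload["spec"]["random_effects"])})
    blups = pd.DataFrame(payload["blups"]["values"],
                         index=pd.Index(payload["blups"]["index"], name="id"),
                         columns=payload["blups"]["columns"])
    return SitarFit(
        spec=spec, knots=np.asarray(payload["knots"]),
        coef=np.asarray(payload["coef"]), omega=np.asarray(payload["omega"]),
        sigma=payload["sigma"], blups=blups, loglik=payload["loglik"],
        bic=payload["bic"], converged=payload["converged"],
        n_individuals=payload["n_individuals"],
        n_observations=payload["n_observations"],
        adult_onset_age=payload["adult_onset_age"],
        age_center=payload.get("age_center", 0.0),
        n_iterations=payload["n_iterations"])


# --------------------------------------------------------------------------
# pipeline configuration


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (see docs for the YAML layout)."""

    out_dir: str = "pubsitar_out"
    seed: int = 0
    # either simulate a cohort ...
    simulate: dict = field(default_factory=dict)  # SimConfig keyword overrides
    # ... or read existing tables
    measurements_path: str | None = None
    covariates_path: str | None = None
    # analysis flags
    select_knots: bool = False
    outlier_sensitivity: bool = False
    associate: bool = True
    grs_columns: tuple = ("grs_puberty", "grs_bmi")
    bodycomp_columns: tuple = ("fmi_z", "lmi_z")
    confounder_columns: tuple = ("fmi_age_y", "maternal_age",
                                 "maternal_education", "parity",
                                 "maternal_bmi_z", "maternal_smoking",
                                 "child_energy_kj")
    measure_models: dict = field(default_factory=dict)  # per-measure overrides

    def __post_init__(self):
        if self.measurements_path is None and self.simulate is None:
            raise ConfigError("either simulate settings or measurements_path "
                              "must be provided")


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
    for tup_field in ("grs_columns", "bodycomp_columns", "confounder_columns"):
        if tup_field in raw and raw[tup_field] is not None:
            raw[tup_field] = tuple(raw[tup_field])
    return PipelineConfig(**raw)


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the configuration for provenance manifests."""
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
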