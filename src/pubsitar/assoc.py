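"""Downstream association statistics for pubertal-age measures.

Implements the analyses that sit on top of the derived pubertal ages:

* genetic risk scores (GRS): weighted mean of effect-allele dosages over a
  SNP set, raw score = sum_j dosage_ij * w_j / m, standardized to mean 0 /
  SD 1 before analysis;
* pairwise Pearson correlations between pubertal-age measures on the
  complete-case subset;
* univariable linear regressions of each pubertal age on a standardized
  GRS (years per SD);
* multivariable linear regressions of pubertal age on fat or lean mass
  index in age- and sex-specific SD units, adjusted for confounders.

Ordinary least squares is delegated to statsmodels; confidence intervals
use the normal approximation beta +/- 1.96 SE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import CollinearityError, DataError

__all__ = [
    "AssociationResult", "build_grs", "fat_mass_index",
    "pairwise_correlations", "regress_univariable", "standardize_by_group",
    "regress_adjusted",
]


@dataclass
class AssociationResult:
    """One regression (or slope) result: estimate, SE, 95% CI, n."""

    exposure: str
    outcome: str
    beta: float
    se: float
    n: int
    covariates: tuple = field(default_factory=tuple)

    @property
    def ci(self) -> tuple[float, float]:
        return (self.beta - 1.96 * self.se, self.beta + 1.96 * self.se)

    def as_row(self) -> dict:
        lcl, ucl = self.ci
        return {"exposure": self.exposure, "outcome": self.outcome,
                "beta": self.beta, "se": self.se, "lcl": lcl, "ucl": ucl,
                "n": self.n, "covariates": ",".join(self.covariates)}


def build_grs(dosages: pd.DataFrame, weights: pd.DataFrame,
              missing: str = "mean") -> pd.DataFrame:
    """Per-individual raw and standardized genetic risk score.

    dosages: individuals x SNPs, entries in [0, 2] (possibly fractional for
    imputed genotypes).  weights: columns snp, effect_allele, weight.  SNPs
    in the weight table but absent from the dosage matrix are excluded with
    a warning and the divisor m reduced accordingly.  Missing dosage
    entries are mean-imputed per SNP (missing='mean') or dropped per
    individual with a per-individual divisor (missing='drop').
    """
    for col in ("snp", "weight"):
        if col not in weights.columns:
            raise DataError(f"weights table missing column '{col}'")
    if weights["snp"].duplicated().any():
        raise DataError("weights table has duplicate SNP ids")
    if not np.all(np.isfinite(weights["weight"].to_numpy(float))):
        raise DataError("weights must be finite")
    if missing not in ("mean", "drop"):
        raise DataError("missing must be 'mean' or 'drop'")

    snps = [s for s in weights["snp"] if s in dosages.columns]
    absent = [s for s in weights["snp"] if s not in dosages.columns]
    if absent:
        warnings.warn(f"{len(absent)} weight SNP(s) absent from dosages, "
                      f"excluded: {absent[:5]}{'...' if len(absent) > 5 else ''}")
    if not snps:
        raise DataError("no usable SNPs shared between weights and dosages")

    D = dosages[snps].to_numpy(float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(D) < 0 or np.nanmax(D) > 2:
            raise DataError("dosages must lie in [0, 2]")
    w = weights.set_index("snp").loc[snps, "weight"].to_numpy(float)
    m = len(snps)
    obs = np.isfinite(D)
    if missing == "mean":
        col_mean = np.where(obs.any(axis=0), np.nanmean(D, axis=0), 0.0)
        D = np.where(obs, D, col_mean[None, :])
        raw = D @ w / m
    else:
        raw = np.where(obs, D, 0.0) @ w / np.maximum(obs.sum(axis=1), 1)
    sd = raw.std(ddof=1)
    if sd == 0:
        std = np.zeros_like(raw)
    else:
        std = (raw - raw.mean()) / sd
    return pd.DataFrame({"raw": raw, "standardized": std},
                        index=dosages.index)


def fat_mass_index(mass_kg, height_m):
    """Fat (or lean) mass index: mass / height^2, kg/m^2."""
    return np.asarray(mass_kg, float) / np.asarray(height_m, float) ** 2


def pairwise_correlations(table: pd.DataFrame,
                          columns=None) -> tuple[pd.DataFrame, int]:
    """Pearson correlations between pubertal-age measures, complete cases.

    Restricts to individuals with non-missing values on every selected
    column, then computes the full symmetric correlation matrix.  Returns
    (matrix, n).  Zero-variance columns yield NaN rows/columns.
    """
    meta = {"id", "sex"}
    if columns is None:
        columns = [c for c in table.columns if c not in meta]
    sub = table[list(columns)].dropna()
    if len(sub) < 3:
        raise DataError("fewer than 3 complete cases for correlation")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = sub.corr(method="pearson")
    zero_var = sub.std(ddof=1) == 0
    if zero_var.any():
        warnings.warn("zero-variance column(s): "
                      f"{list(sub.columns[zero_var])}; correlations undefined")
    return corr, len(sub)


def regress_univariable(outcome, exposure, *, outcome_name: str = "outcome",
                        exposure_name: str = "exposure") -> AssociationResult:
    """OLS of a pubertal age (years) on a standardized exposure."""
    y = np.asarray(outcome, float)
    x = np.asarray(exposure, float)
    keep = np.isfinite(y) & np.isfinite(x)
    y, x = y[keep], x[keep]
    if y.size < 3:
        raise DataError("fewer than 3 paired observations")
    if np.ptp(x) == 0:
        raise DataError("exposure is constant")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return AssociationResult(exposure=exposure_name, outcome=outcome_name,
                             beta=float(model.params[1]),
                             se=float(model.bse[1]), n=int(y.size))


def standardize_by_group(values, groups) -> pd.Series:
    """Z-scores within groups (e.g. sex x age-band): mean 0, SD 1 in each.

    Singleton groups get missing z-scores with a warning."""
    s = pd.Series(np.asarray(values, float))
    g = pd.Series(np.asarray(groups)).reindex(s.index)
    counts = s.groupby(g).transform("count")
    if (counts < 2).any():
        warnings.warn("singleton group(s) produce missing z-scores")
    mean = s.groupby(g).transform("mean")
    sd = s.groupby(g).transform(lambda v: v.std(ddof=1))
    z = (s - mean) / sd
    z[counts < 2] = np.nan
    return z


def regress_adjusted(outcome, exposure, covariates: pd.DataFrame | None = None,
                     *, outcome_name: str = "outcome",
                     exposure_name: str = "exposure") -> AssociationResult:
    """OLS partial slope of pubertal age on exposure, adjusted for
    covariates (complete cases).  With an empty covariate set this
    reproduces `regress_univariable` exactly.

    Raises CollinearityError naming the offending columns when the design
    is rank deficient.
    """
    y = pd.Series(np.asarray(outcome, float)).reset_index(drop=True)
    x = pd.Series(np.asarray(exposure, float)).reset_index(drop=True)
    if covariates is None or (hasattr(covariates, "empty") and covariates.empty):
        cov = pd.DataFrame(index=y.index)
    else:
        cov = pd.DataFrame(covariates).reset_index(drop=True).astype(float)
    design = pd.concat([x.rename(exposure_name), cov], axis=1)
    frame = pd.concat([y.rename("__y"), design], axis=1).dropna()
    if len(frame) <= design.shape[1] + 1:
        raise DataError("not enough complete cases for the adjusted model")
    Xmat = sm.add_constant(frame[design.columns])
    rank = np.linalg.matrix_rank(Xmat.to_numpy())
    if rank < Xmat.shape[1]:
        offenders = _collinear_columns(Xmat)
        raise CollinearityError(
            f"design matrix is rank deficient; suspect columns: {offenders}")
    model = sm.OLS(frame["__y"], Xmat).fit()
    return AssociationResult(
        exposure=exposure_name, outcome=outcome_name,
        beta=float(model.params[exposure_name]),
        se=float(model.bse[exposure_name]), n=int(len(frame)),
        covariates=tuple(cov.columns.astype(str)))


def _collinear_columns(X: pd.DataFrame) -> list:
    """Name columns involved in exact linear dependence (for error text)."""
    cols = list(X.columns)
    offenders = []
    arr = X.to_numpy()
    base_rank = np.linalg.matrix_rank(arr)
    for j, c in enumerate(cols):
        sub = np.delete(arr, j, axis=1)
        if np.linalg.matrix_rank(sub) == base_rank:
            offenders.append(c)
    return offenders or cols
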