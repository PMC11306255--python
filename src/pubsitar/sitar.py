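"""SITAR: shape-invariant nonlinear mixed-effects growth model.

The model for individual i observed at ages t_ij is

    y_ij = alpha_i + h(exp(gamma_i) * (t_ij - c - beta_i) + c)
           + delta_i * (t_ij - t_adult)_+  + e_ij,

where h is a natural cubic spline fitted to the whole sample (internal
knots at quantiles of the age distribution, linear beyond the boundary
knots), c is the mean observed age (the pivot of the intensity stretch,
which makes gamma a local rotation of the curve in the observation
window), and the individual random effects — size alpha (vertical shift),
timing beta (left-right shift, years), intensity gamma (log age-scale
stretch) and post-growth slope delta (individual adult slope, applied
beyond the adult-onset age t_adult taken as the last internal knot) — are
jointly Gaussian with unstructured covariance Omega.  Any non-empty subset
of the four effects may be requested; the reduced two-effect model
(timing + intensity, no size) is appropriate for ordinal development
scores where every individual moves over the same bounded scale.

Estimation is iterated first-order conditional linearization: a penalized
nonlinear least-squares (Gauss-Newton) step updates the fixed spline
coefficients and the per-individual effect modes jointly, then the model is
linearized about those modes and the variance components are updated by
maximizing the profiled marginal Gaussian likelihood over the log-Cholesky
factor of Omega/sigma^2 (residual variance and fixed effects profiled out in
closed form).  The two steps alternate to convergence of the approximate
marginal log-likelihood.  All per-individual linear algebra is batched,
which keeps cohorts of a few thousand individuals in the seconds range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize, minimize_scalar

from .basis import NaturalCubicSpline
from .exceptions import ConfigError, DataError, FitError, LandmarkError

__all__ = [
    "EFFECTS", "SitarSpec", "SitarFit", "OutlierReport",
    "fit_sitar", "select_model", "predict_curves",
    "age_at_peak_velocity", "age_at_level", "individual_pubertal_age",
    "remove_outliers",
]

EFFECTS = ("size", "timing", "intensity", "postgrowth")


@dataclass(frozen=True)
class SitarSpec:
    """Configuration of one SITAR fit."""

    outcome: str = ""
    random_effects: tuple = ("size", "timing", "intensity")
    n_knots: int = 4
    max_iter: int = 60
    min_iter: int = 4  # outer iterations before convergence may be declared
    tol: float = 1e-7  # relative change in marginal log-likelihood
    bic_n: str = "individuals"  # or "observations": the n used in BIC

    def __post_init__(self):
        if not 2 <= self.n_knots <= 5:
            raise ConfigError("n_knots must be between 2 and 5")
        effs = tuple(self.random_effects)
        if not effs:
            raise ConfigError("random_effects must be non-empty")
        bad = set(effs) - set(EFFECTS)
        if bad:
            raise ConfigError(f"unknown random effects: {sorted(bad)}")
        if len(set(effs)) != len(effs):
            raise ConfigError("random_effects contains duplicates")
        # canonical ordering
        object.__setattr__(self, "random_effects",
                           tuple(e for e in EFFECTS if e in effs))
        if self.bic_n not in ("individuals", "observations"):
            raise ConfigError("bic_n must be 'individuals' or 'observations'")


@dataclass
class SitarFit:
    """A fitted SITAR model.

    coef[0] is the fixed intercept; coef[1:] are the natural-spline
    coefficients of the mean curve h.  blups holds the empirical-Bayes
    (shrunken) per-individual random effects in natural units (size in
    outcome units, timing in years, intensity on the log scale, postgrowth
    in outcome units per year).
    """

    spec: SitarSpec
    knots: np.ndarray
    coef: np.ndarray
    omega: np.ndarray
    sigma: float
    blups: pd.DataFrame
    loglik: float
    bic: float
    converged: bool
    n_individuals: int
    n_observations: int
    adult_onset_age: float | None = None
    age_center: float = 0.0
    n_iterations: int = 0

    @property
    def effects(self) -> tuple:
        return self.spec.random_effects

    def _spline(self) -> NaturalCubicSpline:
        return NaturalCubicSpline(self.knots)

    def distance(self, ages) -> np.ndarray:
        """Fitted mean distance curve at `ages` (years)."""
        ages = np.asarray(ages, float)
        B = self._spline().design(ages)
        return self.coef[0] + B @ self.coef[1:]

    def velocity(self, ages) -> np.ndarray:
        """Analytic first derivative of the fitted mean curve."""
        ages = np.asarray(ages, float)
        B1 = self._spline().design(ages, order=1)
        return B1 @ self.coef[1:]

    def predict_individual(self, individual_id, ages) -> np.ndarray:
        """Individual curve from the fitted mean curve and the BLUPs."""
        u = self.blups.loc[individual_id]
        alpha = u.get("size", 0.0)
        beta = u.get("timing", 0.0)
        gamma = u.get("intensity", 0.0)
        delta = u.get("postgrowth", 0.0)
        ages = np.asarray(ages, float)
        c0 = self.age_center
        x = np.exp(gamma) * (ages - c0 - beta) + c0
        B = self._spline().design(x)
        y = alpha + self.coef[0] + B @ self.coef[1:]
        if self.adult_onset_age is not None and delta != 0.0:
            y = y + delta * np.maximum(ages - self.adult_onset_age, 0.0)
        return y


@dataclass
class OutlierReport:
    n_removed: int
    n_total: int

    @property
    def pct_removed(self) -> float:
        return 100.0 * self.n_removed / self.n_total if self.n_total else 0.0


# --------------------------------------------------------------------------
# data preparation


def _extract_columns(data: pd.DataFrame, outcome: str = ""):
    """Pull (id, age_years, value) out of a long measurement table.

    Accepts age in months ('age_months', the storage convention) or years
    ('age_y').  If an 'measure' column is present and `outcome` is set, the
    table is filtered to that measure.
    """
    df = data
    if "measure" in df.columns and outcome:
        df = df[df["measure"] == outcome]
    if "age_months" in df.columns:
        age = df["age_months"].to_numpy(float) / 12.0
    elif "age_y" in df.columns:
        age = df["age_y"].to_numpy(float)
    else:
        raise DataError("measurement table needs an 'age_months' or 'age_y' column")
    for col in ("id", "value"):
        if col not in df.columns:
            raise DataError(f"measurement table missing column '{col}'")
    y = df["value"].to_numpy(float)
    ids = df["id"].to_numpy()
    keep = np.isfinite(y) & np.isfinite(age)
    if not keep.any():
        raise DataError("no non-missing observations for the outcome")
    return ids[keep], age[keep], y[keep]


class _Groups:
    """Sort observations by individual and expose equal-size batches."""

    def __init__(self, ids):
        uniq, codes = np.unique(ids, return_inverse=True)
        order = np.argsort(codes, kind="stable")
        counts = np.bincount(codes)
        offsets = np.concatenate([[0], np.cumsum(counts)])
        self.unique_ids = uniq
        self.codes = codes
        self.n_ind = uniq.size
        self.batches = []  # (ind_idx (m,), obs_idx (m, s)) in sorted-obs space
        for s in np.unique(counts):
            members = np.nonzero(counts == s)[0]
            obs_idx = offsets[members][:, None] + np.arange(s)[None, :]
            self.batches.append((members, order[obs_idx]))

    def products(self, X, Z, v):
        """Per-individual Z'Z, Z'X, Z'v stacked in individual order."""
        n, q, p = self.n_ind, Z.shape[1], X.shape[1]
        ZtZ = np.empty((n, q, q))
        ZtX = np.empty((n, q, p))
        Ztv = np.empty((n, q))
        for members, obs in self.batches:
            Zg = Z[obs]
            ZtZ[members] = np.einsum("msq,msr->mqr", Zg, Zg)
            ZtX[members] = np.einsum("msq,msp->mqp", Zg, X[obs])
            Ztv[members] = np.einsum("msq,ms->mq", Zg, v[obs])
        return ZtZ, ZtX, Ztv


# --------------------------------------------------------------------------
# model terms


def _terms(c, u, t, spline, effects, onset, groups, center=0.0):
    """Model values and Jacobians at the current estimates.

    Returns f (n_obs,), X (n_obs, p) Jacobian wrt fixed effects and
    Z (n_obs, q) Jacobian wrt the random effects (canonical effect order).
    The intensity stretch pivots around `center` (the mean observed age),
    so it acts as a local rotation of the curve in the observation window.
    """
    uo = u[groups.codes]  # expand to per-observation
    idx = {e: j for j, e in enumerate(effects)}
    alpha = uo[:, idx["size"]] if "size" in idx else 0.0
    beta = uo[:, idx["timing"]] if "timing" in idx else 0.0
    gamma = uo[:, idx["intensity"]] if "intensity" in idx else 0.0
    delta = uo[:, idx["postgrowth"]] if "postgrowth" in idx else 0.0

    eg = np.exp(gamma) if "intensity" in idx else 1.0
    x = eg * (t - center - beta) + center
    B = spline.design(x)
    hp = spline.design(x, order=1) @ c[1:]
    f = c[0] + B @ c[1:]
    if "size" in idx:
        f = f + alpha
    pg = None
    if "postgrowth" in idx:
        pg = np.maximum(t - onset, 0.0)
        f = f + delta * pg

    X = np.column_stack([np.ones_like(t), B])
    cols = []
    for e in effects:
        if e == "size":
            cols.append(np.ones_like(t))
        elif e == "timing":
            cols.append(-eg * hp)
        elif e == "intensity":
            cols.append((x - center) * hp)
        else:  # postgrowth
            cols.append(pg)
    Z = np.column_stack(cols)
    return f, X, Z


# --------------------------------------------------------------------------
# estimation steps


def _pnls(c, u, L, t, y, spline, effects, onset, groups, center=0.0,
          max_inner=40):
    """Joint penalized Gauss-Newton update of (fixed coefs, effect modes).

    Minimizes ||y - f(c, u)||^2 + sum_i u_i' Delta^{-1} u_i with
    Delta = L L' the relative (to sigma^2) covariance of the effects.
    """
    q = len(effects)
    Linv = np.linalg.inv(L)
    P = Linv.T @ Linv  # Delta^{-1}

    def objective(c_, u_):
        f, _, _ = _terms(c_, u_, t, spline, effects, onset, groups, center)
        r = y - f
        return float(r @ r + np.einsum("nq,qr,nr->", u_, P, u_))

    obj = objective(c, u)
    for _ in range(max_inner):
        f, X, Z = _terms(c, u, t, spline, effects, onset, groups, center)
        r = y - f
        ZtZ, ZtX, Ztr = groups.products(X, Z, r)
        G = ZtZ + P[None]
        rhs = Ztr - u @ P
        Gi_rhs = np.linalg.solve(G, rhs[:, :, None])[:, :, 0]
        Gi_ZtX = np.linalg.solve(G, ZtX)
        S = X.T @ X - np.einsum("nqp,nqr->pr", ZtX, Gi_ZtX)
        b = X.T @ r - np.einsum("nqp,nq->p", ZtX, Gi_rhs)
        try:
            dc = np.linalg.solve(S, b)
        except np.linalg.LinAlgError:
            dc = np.linalg.lstsq(S, b, rcond=None)[0]
        du = Gi_rhs - np.einsum("nqp,p->nq", Gi_ZtX, dc)

        step, improved = 1.0, False
        for _ in range(10):
            new_obj = objective(c + step * dc, u + step * du)
            if np.isfinite(new_obj) and new_obj <= obj:
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        c = c + step * dc
        u = u + step * du
        if obj - new_obj < 1e-10 * (1.0 + abs(obj)):
            obj = new_obj
            break
        obj = new_obj
    return c, u


def _pack(L):
    q = L.shape[0]
    theta = [math.log(max(L[j, j], 1e-12)) for j in range(q)]
    for i in range(1, q):
        theta.extend(L[i, :i])
    return np.array(theta)


def _unpack(theta, q):
    L = np.zeros((q, q))
    for j in range(q):
        L[j, j] = math.exp(min(theta[j], 40.0))
    k = q
    for i in range(1, q):
        L[i, :i] = theta[k:k + i]
        k += i
    return L


def _lme_surface(c, u, t, y, spline, effects, onset, groups, center=0.0):
    """Profiled marginal log-likelihood surface of the model linearized
    at (c, u): a closure over theta (log-Cholesky of Delta = Omega/sigma^2)
    with GLS fixed effects and sigma^2 profiled out in closed form."""
    q = len(effects)
    f, X, Z = _terms(c, u, t, spline, effects, onset, groups, center)
    w = y - f + X @ c + np.einsum("nq,nq->n", Z, u[groups.codes])
    ZtZ, ZtX, Ztw = groups.products(X, Z, w)
    XtX = X.T @ X
    Xtw = X.T @ w
    wtw = float(w @ w)
    N = y.size
    Iq = np.eye(q)

    p1 = XtX.shape[0]
    bad = (np.inf, np.zeros(q * (q + 1) // 2))

    def profile(theta, want_state=False):
        """nll and its analytic gradient wrt theta (or the fit state).

        Gradient: with M = 0.5 * sum_i (Z'V^-1 Z - Z'V^-1 r r'V^-1 Z /
        sigma^2) (fixed effects and sigma^2 profiled out; envelope theorem
        kills their derivative terms), d nll/dL = 2 M L, chained through
        the log-diagonal parameterization.
        """
        Lc = _unpack(theta, q)
        Bm = Iq[None] + (Lc.T @ ZtZ) @ Lc
        try:
            ch = np.linalg.cholesky(Bm)
        except np.linalg.LinAlgError:
            return (np.inf, None) if want_state else bad
        logdet = 2.0 * np.log(np.diagonal(ch, axis1=1, axis2=2)).sum()
        LtZtX = Lc.T @ ZtX  # (n, q, p+1 fixed cols)
        LtZtw = Ztw @ Lc
        rhs = np.concatenate([LtZtX, LtZtw[:, :, None]], axis=2)
        sol = np.linalg.solve(Bm, rhs)
        BiX, Biw = sol[:, :, :p1], sol[:, :, p1]
        flatL = LtZtX.reshape(-1, p1)
        XtVX = XtX - flatL.T @ BiX.reshape(-1, p1)
        XtVw = Xtw - flatL.T @ Biw.ravel()
        wtVw = wtw - float(LtZtw.ravel() @ Biw.ravel())
        try:
            chat = np.linalg.solve(XtVX, XtVw)
        except np.linalg.LinAlgError:
            return (np.inf, None) if want_state else bad
        rss = wtVw - XtVw @ chat
        if not np.isfinite(rss) or rss <= 0:
            return (np.inf, None) if want_state else bad
        sigma2 = rss / N
        nll = 0.5 * (N * math.log(2.0 * math.pi * sigma2) + N + logdet)
        if want_state:
            resid_q = Ztw - ZtX @ chat
            ub = (np.linalg.solve(Bm, (resid_q @ Lc)[:, :, None])[:, :, 0]
                  @ Lc.T)
            return nll, (chat, math.sqrt(sigma2), Lc, ub)

        # analytic gradient
        Ztr = Ztw - ZtX @ chat  # (n, q): Z_i' r_i at the GLS fit
        # A_i = Z'V^-1 Z = ZtZ - ZtZ L B^-1 L' ZtZ
        LtZtZ = Lc.T @ ZtZ  # (n, q, q)
        A = ZtZ - np.swapaxes(LtZtZ, 1, 2) @ np.linalg.solve(Bm, LtZtZ)
        # b_i = Z'V^-1 r_i = Ztr - ZtZ L B^-1 L' Ztr
        Ltr = Ztr @ Lc
        tmp = np.linalg.solve(Bm, Ltr[:, :, None])[:, :, 0]
        b = Ztr - np.einsum("nrq,nr->nq", LtZtZ, tmp)
        M = 0.5 * (A.sum(axis=0) - (b.T @ b) / sigma2)
        GL = 2.0 * M @ Lc
        grad = np.empty(theta.size)
        for j in range(q):
            grad[j] = GL[j, j] * Lc[j, j]
        k = q
        for i in range(1, q):
            grad[k:k + i] = GL[i, :i]
            k += i
        return nll, grad

    return profile


def _theta_bounds(npar, q):
    return [(-12.0, 8.0)] * q + [(-60.0, 60.0)] * (npar - q)


def _lme(c, u, L, t, y, spline, effects, onset, groups, center=0.0):
    """Variance-component update: maximize the profiled marginal
    log-likelihood of the linearized model over theta.  Returns updated
    (c, u, L, sigma, ll)."""
    q = len(effects)
    profile = _lme_surface(c, u, t, y, spline, effects, onset, groups, center)
    theta0 = _pack(L)
    res = minimize(profile, theta0, method="L-BFGS-B", jac=True,
                   bounds=_theta_bounds(theta0.size, q),
                   options={"maxiter": 200, "ftol": 1e-14, "gtol": 1e-10})
    theta = res.x if np.isfinite(res.fun) else theta0
    nll, state = profile(theta, want_state=True)
    if state is None:
        raise FitError("variance-component update failed (singular profile)")
    chat, sigma, Lc, ub = state
    return chat, ub, Lc, sigma, -nll


def _initial_state(t, y, spline, effects, onset, groups, center=0.0):
    """OLS mean curve plus per-individual ridge pre-estimates of the
    effects (first-order expansion of the model at u=0), which seed both
    the effect modes and the relative variance scales."""
    q = len(effects)
    u = np.zeros((groups.n_ind, q))
    f0, X, Z = _terms(np.zeros(spline.n_columns + 1), u, t, spline, effects,
                      onset, groups, center)
    c, *_ = np.linalg.lstsq(X, y, rcond=None)
    # Jacobian at u=0 with the OLS curve in place
    f0, X, Z = _terms(c, u, t, spline, effects, onset, groups, center)
    r = y - f0
    ZtZ, _, Ztr = groups.products(X, Z, r)
    # per-column ridge keeps individuals with few or uninformative points sane
    col_scale = np.maximum(np.einsum("nqq->q", ZtZ) / groups.n_ind, 1e-12)
    G = ZtZ + 0.25 * np.diag(col_scale)[None]
    u0 = np.linalg.solve(G, Ztr[:, :, None])[:, :, 0]
    resid = r - np.einsum("nq,nq->n", Z, u0[groups.codes])
    sigma0 = max(float(resid.std()), 1e-8)
    sds = np.maximum(u0.std(axis=0), 1e-6)
    # deliberately overdispersed start: shrinking from above is reliable,
    # while understated effect variances can trap the outer loop in a
    # degenerate optimum with the timing variation absorbed into sigma
    L = 2.0 * np.diag(sds / sigma0)
    return c, u0, L, sigma0


def fit_sitar(data: pd.DataFrame, spec: SitarSpec) -> SitarFit:
    """Fit a SITAR model to one measure's long-format data.

    `data` needs columns id, value and age_months (or age_y); rows with
    missing values are dropped.  Non-convergence within spec.max_iter
    returns a fit flagged converged=False with a warning.
    """
    ids, t_abs, y = _extract_columns(data, spec.outcome)
    # the fit runs entirely on age offsets from the youngest observation,
    # quantized at nanoyear resolution: datasets that differ only by a
    # global time translation then yield bitwise-identical internal
    # problems, making the fit exactly translation-equivariant instead of
    # equivariant only up to float rounding (which weakly identified
    # variants can amplify along flat likelihood directions)
    t_ref = float(t_abs.min())
    t = np.round((t_abs - t_ref) * 1e9) / 1e9
    groups = _Groups(ids)
    spline = NaturalCubicSpline.from_quantiles(t, spec.n_knots)
    # adult-slope onset: last internal knot keeps the effect identifiable
    # from the observations in the top tail of the age range
    onset = float(spline.knots[-2]) if "postgrowth" in spec.random_effects else None
    effects = spec.random_effects

    center = float(t.mean())
    c, u, L, _ = _initial_state(t, y, spline, effects, onset, groups, center)
    ll_prev = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, spec.max_iter + 1):
        c, u = _pnls(c, u, L, t, y, spline, effects, onset, groups, center)
        c, u, L, sigma, ll = _lme(c, u, L, t, y, spline, effects, onset,
                                  groups, center)
        if (n_iter >= spec.min_iter
                and abs(ll - ll_prev) < spec.tol * (1.0 + abs(ll))):
            converged = True
            break
        ll_prev = ll
    if not converged:
        warnings.warn(
            f"SITAR fit for '{spec.outcome or 'outcome'}' did not converge "
            f"in {spec.max_iter} iterations", RuntimeWarning)

    omega = sigma**2 * (L @ L.T)
    blups = pd.DataFrame(u, index=pd.Index(groups.unique_ids, name="id"),
                         columns=list(effects))
    q = len(effects)
    p_eff = (spec.n_knots + 2) + q * (q + 1) // 2 + 1
    n_bic = groups.n_ind if spec.bic_n == "individuals" else y.size
    bic = -2.0 * ll + p_eff * math.log(n_bic)
    # map the offset-space fit back to absolute age: knots and pivots
    # shift by t_ref; the intercept absorbs the linear basis column's
    # contribution c[1] * t_ref (N_1(x) = x); all other columns are
    # translation-invariant
    coef_abs = np.asarray(c, float).copy()
    coef_abs[0] -= coef_abs[1] * t_ref
    return SitarFit(spec=spec, knots=spline.knots + t_ref, coef=coef_abs,
                    omega=omega, sigma=float(sigma), blups=blups,
                    loglik=float(ll), bic=float(bic), converged=converged,
                    n_individuals=groups.n_ind, n_observations=int(y.size),
                    adult_onset_age=(None if onset is None else onset + t_ref),
                    age_center=center + t_ref, n_iterations=n_iter)


def select_model(data: pd.DataFrame, spec: SitarSpec,
                 knot_candidates=(2, 3, 4, 5)):
    """Fit over candidate knot counts and pick the converged fit with the
    lowest BIC (ties go to fewer knots).  Returns (best fit, BIC table)."""
    fits, rows = {}, []
    for k in knot_candidates:
        trial = replace(spec, n_knots=k)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = fit_sitar(data, trial)
        except (FitError, DataError, np.linalg.LinAlgError) as exc:
            rows.append({"n_knots": k, "converged": False,
                         "loglik": np.nan, "bic": np.nan, "error": str(exc)})
            continue
        fits[k] = fit
        rows.append({"n_knots": k, "converged": fit.converged,
                     "loglik": fit.loglik, "bic": fit.bic, "error": ""})
    table = pd.DataFrame(rows)
    usable = {k: f for k, f in fits.items() if f.converged}
    if not usable:
        raise FitError("no candidate knot count produced a converged fit")
    best_k = min(usable, key=lambda k: (usable[k].bic, k))
    return usable[best_k], table


# --------------------------------------------------------------------------
# derived quantities


def predict_curves(fit: SitarFit, ages):
    """Mean distance curve and its analytic velocity at `ages` (years)."""
    return fit.distance(ages), fit.velocity(ages)


def age_at_peak_velocity(fit: SitarFit, grid_step: float = 0.01) -> float:
    """Age (years) at the interior maximum of the mean velocity curve.

    Dense-grid search over the knot range followed by local refinement.
    Raises LandmarkError when the maximum sits on the boundary (no interior
    growth spurt peak).
    """
    lo, hi = float(fit.knots[0]), float(fit.knots[-1])
    grid = np.arange(lo, hi + grid_step, grid_step)
    v = fit.velocity(grid)
    k = int(np.argmax(v))
    if k == 0 or k == grid.size - 1:
        raise LandmarkError("no interior peak in the velocity curve")
    res = minimize_scalar(lambda a: -float(fit.velocity(a)),
                          bounds=(grid[k - 1], grid[k + 1]), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


def age_at_level(fit: SitarFit, level: float, tol: float = 1e-3) -> float:
    """Smallest age at which the fitted mean curve reaches `level`."""
    lo, hi = float(fit.knots[0]), float(fit.knots[-1])
    grid = np.linspace(lo, hi, 2001)
    d = fit.distance(grid) - level
    sign_change = np.nonzero(np.diff(np.signbit(d)))[0]
    exact = np.nonzero(d == 0.0)[0]
    candidates = []
    if exact.size:
        candidates.append(grid[exact[0]])
    if sign_change.size:
        j = sign_change[0]
        candidates.append(brentq(lambda a: float(fit.distance(a)) - level,
                                 grid[j], grid[j + 1], xtol=tol / 10))
    if not candidates:
        raise LandmarkError(f"mean curve never crosses level {level} "
                            f"within [{lo:.2f}, {hi:.2f}] y")
    return float(min(candidates))


def individual_pubertal_age(fit: SitarFit, landmark_age: float) -> pd.Series:
    """Per-individual pubertal age = landmark age + timing BLUP (years)."""
    if "timing" not in fit.effects:
        raise FitError("fit has no timing random effect")
    ages = landmark_age + fit.blups["timing"]
    ages.name = "pubertal_age_y"
    return ages


def remove_outliers(data: pd.DataFrame, threshold: float = 5.0):
    """Drop observations more than `threshold` SDs from their visit-level
    mean (grouped per sex and assessment occasion, and measure when
    present).  Returns (filtered data, OutlierReport)."""
    if threshold <= 0:
        raise ConfigError("threshold must be > 0")
    group_cols = [c for c in ("measure", "sex", "occasion") if c in data.columns]
    if not group_cols:
        raise DataError("need at least one of measure/sex/occasion to group by")
    g = data.groupby(group_cols)["value"]
    mean = g.transform("mean")
    sd = g.transform("std")
    dev = (data["value"] - mean).abs()
    drop = (dev > threshold * sd) & sd.notna() & (sd > 0)
    report = OutlierReport(n_removed=int(drop.sum()), n_total=int(len(data)))
    return data[~drop].reset_index(drop=True), report
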