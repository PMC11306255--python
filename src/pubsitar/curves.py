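"""Generative mean curves and the SITAR individual-curve transformation.

Two curve families are used by the cohort simulator:

* :class:`SigmoidGrowthCurve` — a continuous distance curve for height,
  weight or bone mineral content: a pre-pubertal growth component that
  switches off smoothly in late adolescence plus a logistic pubertal spurt.
  Both the distance curve and its velocity are analytic, so the true age at
  peak velocity is available to any precision as an oracle.
* :class:`LatentStageCurve` — a monotone logistic "developmental age" curve
  on a K-point ordinal scale (Tanner 5, voice 3, axillary 2), thresholded
  into stages by the simulator.  Its level crossings have a closed-form
  inverse.

The SITAR transformation maps a mean curve h and individual random effects
(size alpha, timing beta, intensity gamma, post-growth delta) to an
individual curve

    y(t) = alpha + h(exp(gamma) * (t - beta)) + delta * (t - t_adult)_+
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit, logit

__all__ = ["SigmoidGrowthCurve", "SplineGrowthCurve", "LatentStageCurve",
           "sitar_generative_curve"]


def _softplus(z):
    # overflow-safe log(1 + exp(z))
    return np.logaddexp(0.0, z)


@dataclass(frozen=True)
class SigmoidGrowthCurve:
    """Distance curve = smoothly-stopping childhood growth + logistic spurt.

    velocity(t) = base_rate * sigmoid((base_stop - t)/base_scale)
               + (spurt_size/spurt_scale) * sigmoid'((t - spurt_age)/spurt_scale)

    ``level_at_7`` anchors the distance curve at age 7 y.
    """

    level_at_7: float  # outcome units at age 7 y
    base_rate: float  # childhood growth rate, units/y
    base_stop: float  # age (y) at which childhood growth switches off
    base_scale: float  # softness of the switch-off (y)
    spurt_size: float  # total gain attributable to the spurt (units)
    spurt_age: float  # centre of the pubertal spurt (y)
    spurt_scale: float  # spurt duration scale (y)

    def _base_antideriv(self, t):
        # antiderivative of base_rate * sigmoid((base_stop - t)/base_scale)
        return self.base_rate * self.base_scale * (
            -_softplus((self.base_stop - np.asarray(t, float)) / self.base_scale)
        )

    def value(self, t):
        t = np.asarray(t, dtype=float)
        base = self._base_antideriv(t) - self._base_antideriv(7.0)
        spurt = self.spurt_size * expit((t - self.spurt_age) / self.spurt_scale)
        spurt7 = self.spurt_size * expit((7.0 - self.spurt_age) / self.spurt_scale)
        return self.level_at_7 + base + spurt - spurt7

    def velocity(self, t):
        t = np.asarray(t, dtype=float)
        base = self.base_rate * expit((self.base_stop - t) / self.base_scale)
        s = expit((t - self.spurt_age) / self.spurt_scale)
        spurt = self.spurt_size / self.spurt_scale * s * (1.0 - s)
        return base + spurt

    def peak_velocity_age(self) -> float:
        """True age at peak velocity, located on the analytic velocity."""
        res = minimize_scalar(
            lambda t: -float(self.velocity(t)),
            bounds=(self.spurt_age - 3.0, self.spurt_age + 3.0),
            method="bounded",
            options={"xatol": 1e-10},
        )
        return float(res.x)


class SplineGrowthCurve:
    """Population distance curve expressed on a natural cubic spline basis.

    This is the curve family the SITAR model itself assumes, so cohorts
    generated from it are exactly well-specified for the fitter.  Velocity
    is the analytic first derivative of the spline (piecewise quadratic),
    and the peak-velocity age is located on that analytic derivative.

    Build one with :meth:`from_function` to project any smooth distance
    curve (e.g. a :class:`SigmoidGrowthCurve`) onto the basis by dense
    least squares.
    """

    def __init__(self, knots, coef):
        from .basis import NaturalCubicSpline  # local to avoid cycle at import

        self.spline = NaturalCubicSpline(knots)
        coef = np.asarray(coef, dtype=float)
        if coef.size != self.spline.n_columns + 1:
            raise ValueError(
                f"coef needs {self.spline.n_columns + 1} entries "
                f"(intercept + basis), got {coef.size}")
        self.coef = coef

    @classmethod
    def from_function(cls, fn, knots, lo=None, hi=None, n_grid=2001):
        """Least-squares projection of `fn` onto the basis over [lo, hi]."""
        knots = np.asarray(knots, dtype=float)
        lo = knots[0] if lo is None else lo
        hi = knots[-1] if hi is None else hi
        grid = np.linspace(lo, hi, n_grid)
        from .basis import NaturalCubicSpline

        spline = NaturalCubicSpline(knots)
        X = np.column_stack([np.ones(grid.size), spline.design(grid)])
        coef, *_ = np.linalg.lstsq(X, np.asarray(fn(grid), float), rcond=None)
        return cls(knots, coef)

    def value(self, t):
        t = np.asarray(t, dtype=float)
        return self.coef[0] + self.spline.design(t) @ self.coef[1:]

    def velocity(self, t):
        t = np.asarray(t, dtype=float)
        return self.spline.design(t, order=1) @ self.coef[1:]

    def peak_velocity_age(self) -> float:
        """Age at the interior maximum of the analytic velocity curve."""
        lo, hi = self.spline.knots[0], self.spline.knots[-1]
        grid = np.linspace(lo, hi, 4001)
        v = self.velocity(grid)
        k = int(np.argmax(v))
        k = min(max(k, 1), grid.size - 2)
        res = minimize_scalar(
            lambda t: -float(self.velocity(t)),
            bounds=(grid[k - 1], grid[k + 1]), method="bounded",
            options={"xatol": 1e-10})
        return float(res.x)


@dataclass(frozen=True)
class LatentStageCurve:
    """Monotone latent development curve 1 -> K on a K-point ordinal scale.

    latent(t) = 1 + (K - 1) * sigmoid((t - onset_age)/scale)

    ``crossing(level)`` returns the age at which the latent curve equals
    `level`; for the scale midpoint ((K+1)/2) this is exactly ``onset_age``.
    """

    n_stages: int
    onset_age: float  # y
    scale: float  # y

    def value(self, t):
        t = np.asarray(t, dtype=float)
        return 1.0 + (self.n_stages - 1) * expit((t - self.onset_age) / self.scale)

    def velocity(self, t):
        t = np.asarray(t, dtype=float)
        s = expit((t - self.onset_age) / self.scale)
        return (self.n_stages - 1) / self.scale * s * (1.0 - s)

    def crossing(self, level: float) -> float:
        """Closed-form inverse: age at which the latent curve equals level."""
        p = (level - 1.0) / (self.n_stages - 1.0)
        if not 0.0 < p < 1.0:
            raise ValueError(f"level {level} outside the open range (1, {self.n_stages})")
        return self.onset_age + self.scale * float(logit(p))

    @property
    def thresholds(self) -> np.ndarray:
        """Stage boundaries at half-integers: K-1 thresholds for K stages."""
        return np.arange(1, self.n_stages) + 0.5


def sitar_generative_curve(mean_curve, alpha, beta, gamma, delta, age,
                           adult_onset_age=None, age_center=0.0):
    """Individual growth curve under the SITAR transformation.

    y(t) = alpha + h(exp(gamma) * (t - c - beta) + c)
           + delta * (t - adult_onset_age)_+

    With all effects zero this returns the mean curve exactly; beta is a
    left-right shift of the curve, gamma a stretch of the age scale
    (pivoting around the age centre c, 0 by default) and alpha a vertical
    shift; delta is an individual adult slope applied beyond
    `adult_onset_age` (ignored when None or delta == 0).  Centring the
    stretch in the middle of the observation window keeps the intensity
    effect a local rotation of the growth curve rather than a dilation
    from birth.
    """
    age = np.asarray(age, dtype=float)
    x = np.exp(gamma) * (age - age_center - beta) + age_center
    y = alpha + mean_curve.value(x)
    if adult_onset_age is not None and np.any(np.asarray(delta) != 0):
        y = y + delta * np.maximum(age - adult_onset_age, 0.0)
    return y
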