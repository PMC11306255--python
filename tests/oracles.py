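"""Independent closed-form oracles used by the test suite.

These deliberately share no code with the fitting machinery they check:
the random-intercept marginal likelihood is evaluated with the
compound-symmetry closed forms (Sherman-Morrison inverse and rank-one
determinant) and maximized by a 1-D golden-section search over the
variance ratio.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar


def random_intercept_ml_loglik(X, y, group_codes):
    """Maximized ML log-likelihood of y = X b + u_g + e, u_g ~ N(0, tau^2).

    Profiles b (GLS) and sigma^2 in closed form for each variance ratio
    psi = tau^2/sigma^2 using V_i^{-1} = I - psi/(1 + n_i psi) J and
    |V_i| = 1 + n_i psi, then searches over log psi.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    codes = np.asarray(group_codes)
    groups = [np.nonzero(codes == g)[0] for g in np.unique(codes)]
    N = y.size

    def profiled_nll(logpsi):
        psi = np.exp(logpsi)
        XtVX = np.zeros((X.shape[1], X.shape[1]))
        XtVy = np.zeros(X.shape[1])
        ytVy = 0.0
        logdet = 0.0
        for idx in groups:
            Xi, yi = X[idx], y[idx]
            ni = len(idx)
            c = psi / (1.0 + ni * psi)
            sx = Xi.sum(axis=0)
            sy = yi.sum()
            XtVX += Xi.T @ Xi - c * np.outer(sx, sx)
            XtVy += Xi.T @ yi - c * sx * sy
            ytVy += yi @ yi - c * sy * sy
            logdet += np.log1p(ni * psi)
        b = np.linalg.solve(XtVX, XtVy)
        rss = ytVy - XtVy @ b
        sigma2 = rss / N
        return 0.5 * (N * np.log(2.0 * np.pi * sigma2) + N + logdet)

    res = minimize_scalar(profiled_nll, bounds=(-25.0, 15.0),
                          method="bounded", options={"xatol": 1e-12})
    # also consider the boundary psi -> 0 (pure OLS)
    return -min(res.fun, profiled_nll(-40.0))
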