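"""Small dense OLS helper shared by the weight regressions and trait scans.

The screening stage runs tens of thousands of small regressions inside the
permutation calibration, so a thin numpy path (QR least squares + classical
covariance) is used instead of constructing a statsmodels model per fit.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def ols_fit(X: np.ndarray, y: np.ndarray):
    """OLS of y on X (X includes the intercept column).

    Returns ``(coef, se, df_resid)``; ``se`` from the classical
    sigma² (X'X)^-1 covariance.  Raises ``np.linalg.LinAlgError`` if X'X is
    singular (e.g. a constant predictor alongside the intercept).
    """
    n, k = X.shape
    if n <= k:
        raise ValueError(f"too few observations ({n}) for {k} parameters")
    xtx = X.T @ X
    xty = X.T @ y
    coef = np.linalg.solve(xtx, xty)
    resid = y - X @ coef
    df = n - k
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    return coef, se, df


def ols_slope_test(X: np.ndarray, y: np.ndarray, col: int):
    """Coefficient, SE and two-sided t-test p-value for column ``col``."""
    coef, se, df = ols_fit(X, y)
    beta, s = float(coef[col]), float(se[col])
    if s == 0.0:
        return beta, s, np.nan
    t = beta / s
    p = 2.0 * stats.t.sf(abs(t), df)
    return beta, s, float(p)


def study_dummies(study: np.ndarray):
    """Intercept + treatment-coded study dummy matrix, and the level order."""
    levels, codes = np.unique(np.asarray(study), return_inverse=True)
    n = len(codes)
    X = np.ones((n, len(levels)), dtype=float)
    # columns 1.. are indicators for levels[1:]
    for j in range(1, len(levels)):
        X[:, j] = codes == j
    return X, levels
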