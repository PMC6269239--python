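"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the code paths of the package under test: the
weighted-least-squares solution comes from the normal equations assembled
by hand, and the overidentification (Sargan) statistic from its textbook
n * R-squared form.
"""

import numpy as np


def wls_normal_equations(alpha, beta_out, sigma):
    """Weighted-least-squares oracle via explicit normal equations.

    Returns ``(coef, cov, rss, slope0, rss0)``: the intercept+slope fit of
    ``beta_out`` on ``alpha`` with weights ``1/sigma**2`` (coefficients,
    known-variance covariance, weighted residual sum of squares) plus the
    slope-only through-origin fit and its weighted RSS.
    """
    alpha = np.asarray(alpha, float)
    beta_out = np.asarray(beta_out, float)
    w = 1.0 / np.asarray(sigma, float) ** 2
    X = np.column_stack([np.ones_like(alpha), alpha])
    A = X.T @ (w[:, None] * X)
    b = X.T @ (w * beta_out)
    coef = np.linalg.solve(A, b)
    resid = beta_out - X @ coef
    rss = float(w @ resid**2)
    cov = np.linalg.inv(A)
    slope0 = float((w * alpha) @ beta_out / ((w * alpha) @ alpha))
    rss0 = float(w @ (beta_out - slope0 * alpha) ** 2)
    return coef, cov, rss, slope0, rss0


def sargan_statistic(G, exposure, outcome, causal_estimate):
    """Classical overidentification statistic: n * R^2 from regressing the
    instrumental-variable residuals on the instruments."""
    G = np.asarray(G, float)
    resid = np.asarray(outcome, float) - causal_estimate * np.asarray(exposure, float)
    resid = resid - resid.mean()
    X = np.column_stack([np.ones(len(resid)), G])
    fitted = X @ np.linalg.lstsq(X, resid, rcond=None)[0]
    r2 = float(fitted @ fitted) / float(resid @ resid)
    return len(resid) * r2
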