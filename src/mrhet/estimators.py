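"""Causal-effect estimators for summary-data Mendelian randomization.

Implements the per-SNP Wald ratio estimates, the fixed-effect
inverse-variance-weighted (IVW) pooled estimate, MR-Egger weighted
regression with an unconstrained intercept, and a two-stage least-squares
estimator on individual-level data used as an independent oracle for the
asymptotic IVW/2SLS equivalence.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .data_model import (
    EggerResult,
    EmptyDataError,
    InsufficientInstrumentsError,
    IvwResult,
    RatioEstimates,
    SingularDesignError,
    SummaryDataSet,
)

__all__ = [
    "compute_ratio_estimates",
    "ivw_estimate",
    "egger_regression",
    "two_stage_least_squares",
    "TwoStageResult",
]


def compute_ratio_estimates(data: SummaryDataSet) -> RatioEstimates:
    """Per-SNP Wald ratios and inverse-variance weights.

    For SNP j, the ratio estimate of the causal effect is
    beta_ratio = beta_out / alpha with variance sigma_out**2 / alpha**2,
    whose reciprocal is the weight w = alpha**2 / sigma_out**2.
    """
    if np.any(data.alpha == 0.0):
        raise ZeroDivisionError("zero-strength instrument; validate the data first")
    return RatioEstimates(
        snp_id=data.snp_id,
        beta_ratio=data.beta_out / data.alpha,
        weight=data.alpha**2 / data.sigma_out**2,
    )


def ivw_estimate(ratios: RatioEstimates) -> IvwResult:
    """Fixed-effect IVW pooled causal estimate.

    The estimate is the weight-weighted mean of the ratio estimates with
    standard error 1/sqrt(sum of weights).  When m >= 2 the Cochran's Q
    heterogeneity fields are populated (see :func:`mrhet.heterogeneity.cochran_q`).
    """
    m = ratios.m
    if m == 0:
        raise EmptyDataError("cannot pool an empty set of ratio estimates")
    w = ratios.weight
    w_sum = float(np.sum(w))
    beta = float(np.sum(w * ratios.beta_ratio) / w_sum)
    se = float(1.0 / np.sqrt(w_sum))
    if m < 2:
        return IvwResult(beta_ivw=beta, se=se, m=m)
    from .heterogeneity import cochran_q  # deferred: heterogeneity imports us

    q = cochran_q(ratios, beta)
    return IvwResult(
        beta_ivw=beta,
        se=se,
        m=m,
        q_stat=q.statistic,
        q_df=q.df,
        q_pvalue=q.pvalue,
        q_contributions=q.contributions,
    )


def orient_positive(data: SummaryDataSet) -> tuple[SummaryDataSet, bool]:
    """Flip the effect allele of SNPs with negative exposure association.

    Jointly negating (alpha, beta_out) for a SNP is a relabelling of its
    effect allele and leaves ratio estimates, weights, IVW and Q unchanged;
    MR-Egger requires all alpha > 0 for the intercept to be identified.
    Returns the oriented dataset and whether any SNP was flipped.
    """
    sign = np.where(data.alpha < 0, -1.0, 1.0)
    flipped = bool(np.any(sign < 0))
    if not flipped:
        return data, False
    oriented = SummaryDataSet(
        snp_id=data.snp_id,
        alpha=data.alpha * sign,
        beta_out=data.beta_out * sign,
        sigma_out=data.sigma_out,
        alpha_se=data.alpha_se,
    )
    return oriented, True


def egger_regression(
    data: SummaryDataSet,
    *,
    random_effects: bool = False,
    t_inference: bool = False,
) -> EggerResult:
    """MR-Egger weighted regression of outcome on exposure associations.

    Fits E[beta_out] = intercept + slope * alpha by weighted least squares
    with weights 1/sigma_out**2, SNPs oriented to positive alpha.  The
    intercept estimates the mean pleiotropic effect; the slope is the
    pleiotropy-adjusted causal estimate.  Rucker's Q' is the weighted
    residual sum of squares on m - 2 degrees of freedom.

    Parameters
    ----------
    random_effects : bool
        Inflate both standard errors by max(1, sqrt(Q'/(m-2)))
        (multiplicative overdispersion).  Default is fixed-effect SEs from
        the known-variance weighted-least-squares covariance.
    t_inference : bool
        Use a t reference distribution with m - 2 df for the intercept
        test instead of the default normal (z) reference.
    """
    m = data.m
    if m < 3:
        raise InsufficientInstrumentsError(
            f"MR-Egger requires at least 3 instruments, got {m}"
        )
    oriented, flipped = orient_positive(data)
    alpha = oriented.alpha
    if np.ptp(alpha) == 0.0:
        raise SingularDesignError(
            "all instrument strengths identical after orientation; "
            "the Egger intercept and slope are not separable"
        )
    weights = 1.0 / oriented.sigma_out**2
    design = sm.add_constant(alpha)
    fit = sm.WLS(oriented.beta_out, design, weights=weights).fit()
    intercept, slope = (float(v) for v in fit.params)

    resid = oriented.beta_out - (intercept + slope * alpha)
    contributions = resid**2 * weights
    q_prime = float(np.sum(contributions))
    df = m - 2
    q_prime_p = float(stats.chi2.sf(q_prime, df))

    # (X' W X)^{-1} is the covariance under known per-SNP variances
    se_fixed = np.sqrt(np.diag(fit.normalized_cov_params))
    if random_effects:
        se_fixed = se_fixed * max(1.0, np.sqrt(q_prime / df))
    intercept_se, slope_se = (float(v) for v in se_fixed)

    z = intercept / intercept_se if intercept_se > 0 else np.inf * np.sign(intercept)
    if t_inference:
        intercept_p = float(2.0 * stats.t.sf(abs(z), df))
    else:
        intercept_p = float(2.0 * stats.norm.sf(abs(z)))

    return EggerResult(
        intercept=intercept,
        slope=slope,
        intercept_se=intercept_se,
        slope_se=slope_se,
        intercept_pvalue=intercept_p,
        q_prime=q_prime,
        q_prime_df=df,
        q_prime_pvalue=q_prime_p,
        q_prime_contributions=contributions,
        orientation_applied=flipped,
        m=m,
        random_effects=random_effects,
        t_inference=t_inference,
    )


class TwoStageResult:
    """Two-stage least-squares causal estimate and standard error."""

    __slots__ = ("estimate", "se")

    def __init__(self, estimate: float, se: float):
        self.estimate = estimate
        self.se = se


def two_stage_least_squares(genotypes, exposure, outcome) -> TwoStageResult:
    """2SLS estimate of the exposure's causal effect on the outcome.

    Stage 1 regresses the exposure on all instruments (with intercept);
    stage 2 regresses the outcome on the fitted exposure.  The standard
    error uses the conventional 2SLS residuals, i.e. the second-stage
    coefficients applied to the *observed* exposure.

    Used as an independent oracle: with uncorrelated instruments and both
    samples drawn from one population, the summary-data IVW estimate is
    asymptotically equivalent to this estimator.
    """
    G = np.atleast_2d(np.asarray(genotypes, dtype=float))
    if G.shape[0] == 1 and np.asarray(exposure).shape[0] != 1:
        G = G.T
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n = x.shape[0]

    design = sm.add_constant(G, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise SingularDesignError("first-stage design is rank deficient")
    stage1 = sm.OLS(x, design).fit()
    x_hat = stage1.fittedvalues
    stage2 = sm.OLS(y, sm.add_constant(x_hat)).fit()
    const, beta = (float(v) for v in stage2.params)

    resid = y - (const + beta * x)
    dof = max(n - 2, 1)
    sigma2 = float(resid @ resid) / dof
    s_xx = float(np.sum((x_hat - x_hat.mean()) ** 2))
    se = float(np.sqrt(sigma2 / s_xx))
    return TwoStageResult(estimate=beta, se=se)
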