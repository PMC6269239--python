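"""Heterogeneity statistics for global and individual pleiotropy detection.

Cochran's Q measures the weighted dispersion of the per-SNP Wald ratios
around the IVW estimate and follows chi-squared(m-1) under the global null
of no horizontal pleiotropy.  Rucker's Q' plays the same role after
MR-Egger adjustment for the mean pleiotropic effect, on chi-squared(m-2).
Each statistic decomposes exactly into per-SNP contributions, which are
approximately chi-squared(1) and drive the individual outlier tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import estimators
from .data_model import (
    ConsistencyError,
    EggerResult,
    InsufficientInstrumentsError,
    IvwResult,
    PleiotropyReport,
    RatioEstimates,
    SummaryDataSet,
)

logger = logging.getLogger(__name__)

__all__ = [
    "HeterogeneityTest",
    "SnpFlags",
    "cochran_q",
    "rucker_q",
    "individual_pleiotropy_test",
    "build_pleiotropy_report",
    "model_hint",
    "remove_outliers_and_refit",
    "OutlierRemovalResult",
]


@dataclass(frozen=True)
class HeterogeneityTest:
    """A global heterogeneity statistic with its exact decomposition."""

    name: str
    statistic: float
    df: int
    pvalue: float
    contributions: np.ndarray


def cochran_q(ratios: RatioEstimates, beta_ivw: float) -> HeterogeneityTest:
    """Cochran's Q = sum_j w_j (beta_ratio_j - beta_ivw)^2, chi2(m-1) null.

    The per-SNP contribution Q_j = w_j (beta_ratio_j - beta_ivw)^2 is
    approximately chi-squared(1) under the null when m is large.
    """
    m = ratios.m
    if m < 2:
        raise InsufficientInstrumentsError("Cochran's Q requires at least 2 SNPs")
    contributions = ratios.weight * (ratios.beta_ratio - beta_ivw) ** 2
    q = float(np.sum(contributions))
    df = m - 1
    return HeterogeneityTest(
        name="cochran_q",
        statistic=q,
        df=df,
        pvalue=float(stats.chi2.sf(q, df)),
        contributions=contributions,
    )


def rucker_q(data: SummaryDataSet, egger: EggerResult) -> HeterogeneityTest:
    """Rucker's Q' — residual heterogeneity after the MR-Egger fit.

    Q'_j = (beta_out_j - intercept - slope * alpha_j)^2 / sigma_out_j^2
    on the (positively oriented) association scale, identically
    w_j (beta_ratio_j - intercept/alpha_j - slope)^2 on the ratio scale.
    Referred to chi-squared(m-2).

    Raises :class:`ConsistencyError` if ``egger`` was not fitted on ``data``.
    """
    if egger.m != data.m:
        raise ConsistencyError(
            f"Egger fit used m={egger.m} SNPs but dataset has m={data.m}"
        )
    oriented, _ = estimators.orient_positive(data)
    resid = oriented.beta_out - (egger.intercept + egger.slope * oriented.alpha)
    contributions = resid**2 / oriented.sigma_out**2
    q_prime = float(np.sum(contributions))
    if not np.isclose(q_prime, egger.q_prime, rtol=1e-8, atol=1e-12):
        raise ConsistencyError(
            "Egger fit does not reproduce on this dataset; "
            "was it computed from different data?"
        )
    df = data.m - 2
    return HeterogeneityTest(
        name="rucker_q_prime",
        statistic=q_prime,
        df=df,
        pvalue=float(stats.chi2.sf(q_prime, df)),
        contributions=contributions,
    )


@dataclass(frozen=True)
class SnpFlags:
    """Per-SNP outlier flags at the uncorrected and Bonferroni thresholds."""

    threshold_uncorrected: float
    threshold_bonferroni: float
    flag_uncorrected: np.ndarray
    flag_bonferroni: np.ndarray
    outlier_index: np.ndarray


def individual_pleiotropy_test(
    contributions, m: int | None = None, fwer: float = 0.05
) -> SnpFlags:
    """Flag SNPs whose heterogeneity contribution is an outlier.

    Each contribution is compared with the chi-squared(1) quantile at level
    ``1 - fwer`` (uncorrected per-test threshold) and ``1 - fwer/m``
    (Bonferroni familywise threshold).  For m=25 and fwer=0.05 these are
    the 95th and 99.8th percentiles.  Outliers are the SNPs above the
    Bonferroni threshold.
    """
    contributions = np.asarray(contributions, dtype=float)
    if m is None:
        m = contributions.shape[0]
    if not 0.0 < fwer < 1.0:
        raise ValueError("fwer must lie strictly between 0 and 1")
    thr_unc = float(stats.chi2.ppf(1.0 - fwer, 1))
    thr_bonf = float(stats.chi2.ppf(1.0 - fwer / m, 1))
    flag_unc = contributions > thr_unc
    flag_bonf = contributions > thr_bonf
    return SnpFlags(
        threshold_uncorrected=thr_unc,
        threshold_bonferroni=thr_bonf,
        flag_uncorrected=flag_unc,
        flag_bonferroni=flag_bonf,
        outlier_index=np.flatnonzero(flag_bonf),
    )


def model_hint(
    q: HeterogeneityTest,
    q_prime: HeterogeneityTest,
    q_flags: SnpFlags,
    q_prime_flags: SnpFlags,
) -> tuple[str, float]:
    """Advisory indicator of whether the Egger model fits better.

    Returns ``("egger-better", Q - Q')`` when some Q contribution exceeds
    the Bonferroni threshold but no Q' contribution does — the pattern of
    outliers that vanish once the mean pleiotropic effect is modelled —
    and ``("neutral", Q - Q')`` otherwise.  The difference Q - Q' is a
    1-df heuristic for directional pleiotropy.  Purely advisory: nothing
    in the toolkit auto-selects a model from it.
    """
    diff = q.statistic - q_prime.statistic
    if bool(q_flags.flag_bonferroni.any()) and not bool(
        q_prime_flags.flag_bonferroni.any()
    ):
        return "egger-better", diff
    return "neutral", diff


def build_pleiotropy_report(
    data: SummaryDataSet,
    ivw: IvwResult,
    egger: EggerResult | None,
    fwer: float = 0.05,
) -> PleiotropyReport:
    """Assemble global p-values, per-SNP flags and the outlier list."""
    q_flags = individual_pleiotropy_test(ivw.q_contributions, data.m, fwer)
    hint = "neutral"
    q_minus_q_prime = None
    qp_pvalue = None
    qp_unc = qp_bonf = None
    if egger is not None:
        qp = rucker_q(data, egger)
        qp_flags = individual_pleiotropy_test(qp.contributions, data.m, fwer)
        q_test = HeterogeneityTest(
            "cochran_q", float(ivw.q_stat), int(ivw.q_df), float(ivw.q_pvalue),
            ivw.q_contributions,
        )
        hint, q_minus_q_prime = model_hint(q_test, qp, q_flags, qp_flags)
        qp_pvalue = qp.pvalue
        qp_unc = qp_flags.flag_uncorrected
        qp_bonf = qp_flags.flag_bonferroni
    return PleiotropyReport(
        m=data.m,
        fwer=fwer,
        global_q_pvalue=float(ivw.q_pvalue),
        global_q_prime_pvalue=qp_pvalue,
        threshold_uncorrected=q_flags.threshold_uncorrected,
        threshold_bonferroni=q_flags.threshold_bonferroni,
        q_flags_uncorrected=q_flags.flag_uncorrected,
        q_flags_bonferroni=q_flags.flag_bonferroni,
        q_prime_flags_uncorrected=qp_unc,
        q_prime_flags_bonferroni=qp_bonf,
        outlier_ids=[str(s) for s in data.snp_id[q_flags.outlier_index]],
        model_hint=hint,
        q_minus_q_prime=q_minus_q_prime,
    )


@dataclass(frozen=True)
class OutlierRemovalResult:
    """Outcome of outlier removal: filtered data, refits, removal trail."""

    data: SummaryDataSet
    ivw: IvwResult
    egger: EggerResult | None
    report: PleiotropyReport
    removed_ids: list
    rounds: int


def remove_outliers_and_refit(
    data: SummaryDataSet,
    report: PleiotropyReport,
    policy: str = "single-pass",
    fwer: float | None = None,
    random_effects: bool = False,
) -> OutlierRemovalResult:
    """Remove Bonferroni-flagged outliers and refit IVW and MR-Egger.

    ``policy`` is ``"single-pass"`` (default) or ``"iterate"``; iterative
    removal repeats until no Bonferroni outliers remain or another round
    would leave fewer than 3 SNPs.  Repeated testing on filtered data no
    longer controls the nominal familywise error rate, so enabling it logs
    a warning.  Refuses outright if removal would leave fewer than 2 SNPs.
    """
    if policy not in ("single-pass", "iterate"):
        raise ValueError(f"unknown outlier policy: {policy!r}")
    if fwer is None:
        fwer = report.fwer
    if policy == "iterate":
        logger.warning(
            "iterative outlier removal repeats per-SNP tests on filtered data; "
            "the nominal FWER no longer applies"
        )

    current = data
    current_report = report
    removed: list = []
    rounds = 0
    while current_report.outlier_ids:
        survivors = current.m - len(current_report.outlier_ids)
        if survivors < 2:
            raise InsufficientInstrumentsError(
                f"removing {len(current_report.outlier_ids)} outlier(s) would "
                f"leave {survivors} SNP(s); at least 2 are required — refusing"
            )
        if rounds > 0 and survivors < 3:
            break  # iterate mode: stop before Egger becomes unfittable
        removed.extend(current_report.outlier_ids)
        logger.info("removing outlier SNP(s): %s", current_report.outlier_ids)
        current = current.drop_snps(current_report.outlier_ids)
        rounds += 1
        ivw = estimators.ivw_estimate(estimators.compute_ratio_estimates(current))
        egger = (
            estimators.egger_regression(current, random_effects=random_effects)
            if current.m >= 3
            else None
        )
        current_report = build_pleiotropy_report(current, ivw, egger, fwer)
        if policy == "single-pass":
            break

    if rounds == 0:  # no outliers: fixed point, return the original fit
        ivw = estimators.ivw_estimate(estimators.compute_ratio_estimates(current))
        egger = (
            estimators.egger_regression(current, random_effects=random_effects)
            if current.m >= 3
            else None
        )
    return OutlierRemovalResult(
        data=current,
        ivw=ivw,
        egger=egger,
        report=current_report,
        removed_ids=removed,
        rounds=rounds,
    )
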