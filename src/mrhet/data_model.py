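"""Domain types and I/O for two-sample summary-data Mendelian randomization.

A :class:`SummaryDataSet` holds, for each of ``m`` independent SNPs, the
SNP-exposure association ``alpha`` (:math:`\\alpha_j`), the SNP-outcome
association ``beta_out`` (:math:`\\hat\\beta_{YG_j}`) and its standard error
``sigma_out`` (:math:`\\sigma_{Y_j}`).  Associations are assumed to be
pre-harmonized to a common effect allele; this module never touches allele
columns.

The interchange format is tab-delimited text with a header row and columns
``snp``, ``beta_exp``, ``se_exp`` (optional), ``beta_out``, ``se_out``.
``NA`` is permitted only in ``se_exp``; a missing or ``NA`` exposure standard
error is interpreted as exactly zero measurement error in the SNP-exposure
association (the strong-instrument / NOME assumption).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("snp", "beta_exp", "beta_out", "se_out")
OPTIONAL_COLUMNS = ("se_exp",)


class SummaryDataError(ValueError):
    """Base class for summary-data problems."""


class DataFormatError(SummaryDataError):
    """The input table does not conform to the interchange dialect."""


class ValidationError(SummaryDataError):
    """The input table parses but violates a dataset invariant."""


class EmptyDataError(SummaryDataError):
    """Too few usable SNPs remain after validation."""


class InsufficientInstrumentsError(SummaryDataError):
    """An operation requires more instruments than the dataset provides."""


class SingularDesignError(SummaryDataError):
    """A regression design matrix is rank deficient (e.g. no variability
    in instrument strength, or perfectly collinear instruments)."""


class ConsistencyError(SummaryDataError):
    """Two objects passed together were not derived from the same data."""


@dataclass(frozen=True)
class SummaryDataSet:
    """Validated per-SNP summary statistics for a two-sample MR analysis.

    Attributes
    ----------
    snp_id : ndarray of str
        Unique variant labels.
    alpha : ndarray of float
        SNP-exposure associations :math:`\\alpha_j` (per-allele effects),
        all nonzero.
    beta_out : ndarray of float
        SNP-outcome associations :math:`\\hat\\beta_{YG_j}`.
    sigma_out : ndarray of float
        Standard errors :math:`\\sigma_{Y_j} > 0` of ``beta_out``.
    alpha_se : ndarray of float, optional
        Standard errors of ``alpha``.  ``None`` means the exposure
        associations are treated as known without error.
    """

    snp_id: np.ndarray
    alpha: np.ndarray
    beta_out: np.ndarray
    sigma_out: np.ndarray
    alpha_se: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("snp_id", "alpha", "beta_out", "sigma_out"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if self.alpha_se is not None:
            object.__setattr__(self, "alpha_se", np.asarray(self.alpha_se, dtype=float))

    @property
    def m(self) -> int:
        """Number of SNPs."""
        return int(self.alpha.shape[0])

    def subset(self, index) -> "SummaryDataSet":
        """Return a new dataset restricted to ``index`` (mask or positions)."""
        index = np.asarray(index)
        return SummaryDataSet(
            snp_id=self.snp_id[index],
            alpha=self.alpha[index],
            beta_out=self.beta_out[index],
            sigma_out=self.sigma_out[index],
            alpha_se=None if self.alpha_se is None else self.alpha_se[index],
        )

    def drop_snps(self, snp_ids) -> "SummaryDataSet":
        """Return a new dataset with the named SNPs removed."""
        keep = ~np.isin(self.snp_id, np.asarray(list(snp_ids)))
        return self.subset(keep)

    def to_frame(self) -> pd.DataFrame:
        """Render as a DataFrame in the interchange column order."""
        frame = pd.DataFrame(
            {
                "snp": self.snp_id,
                "beta_exp": self.alpha,
                "se_exp": np.nan if self.alpha_se is None else self.alpha_se,
                "beta_out": self.beta_out,
                "se_out": self.sigma_out,
            }
        )
        return frame


@dataclass(frozen=True)
class RatioEstimates:
    """Per-SNP Wald ratios and their inverse-variance weights.

    ``beta_ratio[j]`` is :math:`\\hat\\beta_j = \\hat\\beta_{YG_j}/\\alpha_j`
    and ``weight[j]`` is :math:`w_j = \\alpha_j^2/\\sigma_{Y_j}^2`, the
    reciprocal of :math:`\\mathrm{Var}[\\hat\\beta_j]`.
    """

    snp_id: np.ndarray
    beta_ratio: np.ndarray
    weight: np.ndarray

    @property
    def m(self) -> int:
        return int(self.beta_ratio.shape[0])


@dataclass(frozen=True)
class IvwResult:
    """Inverse-variance-weighted causal estimate with Cochran's Q attached.

    ``q_stat`` is :math:`Q=\\sum_j w_j(\\hat\\beta_j-\\hat\\beta_{IVW})^2`,
    referred to a :math:`\\chi^2(m-1)` null; ``q_contributions`` are the
    per-SNP summands :math:`Q_j`.
    """

    beta_ivw: float
    se: float
    m: int
    q_stat: float | None = None
    q_df: int | None = None
    q_pvalue: float | None = None
    q_contributions: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "estimate": self.beta_ivw,
            "se": self.se,
            "ci_low": self.beta_ivw - 1.959963984540054 * self.se,
            "ci_high": self.beta_ivw + 1.959963984540054 * self.se,
            "q": self.q_stat,
            "df": self.q_df,
            "p": self.q_pvalue,
            "contributions": None
            if self.q_contributions is None
            else list(map(float, self.q_contributions)),
        }


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger weighted regression fit with Rucker's Q' attached.

    ``intercept`` estimates the mean pleiotropic effect; ``slope`` is the
    pleiotropy-adjusted causal estimate.  ``q_prime`` is the Egger weighted
    residual sum of squares, referred to a :math:`\\chi^2(m-2)` null.
    """

    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    intercept_pvalue: float
    q_prime: float
    q_prime_df: int
    q_prime_pvalue: float
    q_prime_contributions: np.ndarray
    orientation_applied: bool
    m: int
    random_effects: bool = False
    t_inference: bool = False

    def to_dict(self) -> dict:
        return {
            "estimate": self.slope,
            "se": self.slope_se,
            "ci_low": self.slope - 1.959963984540054 * self.slope_se,
            "ci_high": self.slope + 1.959963984540054 * self.slope_se,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "intercept_p": self.intercept_pvalue,
            "q": self.q_prime,
            "df": self.q_prime_df,
            "p": self.q_prime_pvalue,
            "contributions": list(map(float, self.q_prime_contributions)),
        }


@dataclass(frozen=True)
class PleiotropyReport:
    """Global and per-SNP pleiotropy test results at both thresholds.

    Per-SNP contributions are compared against the :math:`\\chi^2(1)`
    quantile at ``1 - fwer`` (uncorrected) and ``1 - fwer/m`` (Bonferroni);
    ``outlier_ids`` are the SNPs whose Q contribution exceeds the Bonferroni
    threshold and are therefore candidates for removal.
    """

    m: int
    fwer: float
    global_q_pvalue: float
    global_q_prime_pvalue: float | None
    threshold_uncorrected: float
    threshold_bonferroni: float
    q_flags_uncorrected: np.ndarray
    q_flags_bonferroni: np.ndarray
    q_prime_flags_uncorrected: np.ndarray | None
    q_prime_flags_bonferroni: np.ndarray | None
    outlier_ids: list = field(default_factory=list)
    model_hint: str = "neutral"
    q_minus_q_prime: float | None = None


def _as_frame(rows) -> pd.DataFrame:
    if isinstance(rows, pd.DataFrame):
        return rows.copy()
    return pd.DataFrame(list(rows))


def validate_summary_data(rows, strict: bool = False) -> SummaryDataSet:
    """Validate raw summary rows into a :class:`SummaryDataSet`.

    Parameters
    ----------
    rows : DataFrame or iterable of mappings
        Must provide columns ``snp``, ``beta_exp``, ``beta_out``, ``se_out``;
        ``se_exp`` is optional.
    strict : bool
        If True, zero-strength instruments (``beta_exp == 0``) or
        nonpositive ``se_out`` raise instead of being dropped with a warning.

    Raises
    ------
    DataFormatError
        A required column is missing.
    ValidationError
        Duplicate SNP identifiers, a disallowed missing value, or (in
        strict mode) an invalid row.
    EmptyDataError
        Fewer than 2 SNPs survive filtering.
    """
    frame = _as_frame(rows)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise DataFormatError(f"missing required column(s): {', '.join(missing)}")

    ids = frame["snp"].astype(str)
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate snp identifiers: {sorted(set(dup))}")

    for col in ("beta_exp", "beta_out", "se_out"):
        values = pd.to_numeric(frame[col], errors="coerce")
        if values.isna().any():
            raise ValidationError(f"missing or non-numeric values in column {col!r}")
        frame[col] = values

    alpha = frame["beta_exp"].to_numpy(dtype=float)
    sigma = frame["se_out"].to_numpy(dtype=float)

    bad_alpha = alpha == 0.0
    bad_sigma = sigma <= 0.0
    bad = bad_alpha | bad_sigma
    if bad.any():
        offenders = list(ids[bad])
        if strict:
            raise ValidationError(
                f"invalid rows (zero beta_exp or nonpositive se_out): {offenders}"
            )
        logger.warning(
            "dropping %d SNP(s) with zero exposure association or nonpositive "
            "outcome SE: %s",
            int(bad.sum()),
            offenders,
        )
        frame = frame.loc[~bad]

    if len(frame) < 2:
        raise EmptyDataError(
            f"only {len(frame)} usable SNP(s); at least 2 are required"
        )

    alpha_se = None
    if "se_exp" in frame.columns:
        se_exp = pd.to_numeric(frame["se_exp"], errors="coerce")
        if not se_exp.isna().all():
            # missing entries mean "known without error"
            alpha_se = se_exp.fillna(0.0).to_numpy(dtype=float)
            if (alpha_se < 0).any():
                raise ValidationError("negative values in column 'se_exp'")

    return SummaryDataSet(
        snp_id=frame["snp"].astype(str).to_numpy(),
        alpha=frame["beta_exp"].to_numpy(dtype=float),
        beta_out=frame["beta_out"].to_numpy(dtype=float),
        sigma_out=frame["se_out"].to_numpy(dtype=float),
        alpha_se=alpha_se,
    )


def read_summary_data(path, strict: bool = False) -> SummaryDataSet:
    """Read and validate a tab-delimited summary-statistics file."""
    try:
        frame = pd.read_csv(
            path,
            sep="\t",
            na_values=["NA"],
            keep_default_na=False,
            float_precision="round_trip",
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DataFormatError(str(exc)) from exc
    return validate_summary_data(frame, strict=strict)


def write_summary_data(data: SummaryDataSet, path) -> None:
    """Write a dataset in the interchange dialect (round-trips exactly)."""
    frame = data.to_frame()
    # %.17g guarantees every binary double round-trips through decimal text
    frame.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")
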