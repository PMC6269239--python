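"""Seeded generators for synthetic two-sample MR data.

The summary-level generator draws, for each of ``m`` SNPs, an instrument
strength ``alpha_j ~ Uniform(alpha_low, alpha_high)``, an outcome standard
error ``sigma_j ~ Uniform(sigma_low, sigma_high)`` and a pleiotropic effect
``beta2_j`` (zero, balanced or directional), then forms the SNP-outcome
association

    beta_out_j = beta1 * alpha_j + beta2_j + eps_j,   eps_j ~ N(0, sigma_j^2).

Pleiotropic effects are drawn independently of instrument strengths, so the
InSIDE assumption (instrument strength independent of direct effect) holds
by construction.  By default the exposure associations are reported without
error (the NOME assumption); setting ``alpha_se > 0`` adds measurement
noise to the reported alphas while the weights still use the outcome SEs,
reproducing the weak-instrument regime in which Cochran's Q over-rejects.

The individual-level generator draws two disjoint cohorts from one
population (biallelic genotypes, a shared confounder, continuous exposure
and outcome) and derives the same summary statistics by per-SNP marginal
regression, enabling the 2SLS/IVW asymptotic-equivalence checks.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .data_model import SummaryDataSet

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "IndividualData",
    "simulate_summary_data",
    "simulate_individual_data",
    "summary_from_individual",
    "truth_sidecar",
]

PLEIOTROPY_MODES = ("none", "balanced", "directional")


@dataclass(frozen=True)
class SimulationConfig:
    """Data-generating parameters for the synthetic MR datasets.

    Parameters
    ----------
    m : int
        Number of SNP instruments (default 25).
    beta1 : float
        True causal effect of the exposure on the outcome.
    pleiotropy_mode : {"none", "balanced", "directional"}
        "balanced": beta2_j ~ Uniform(-pleio_max, +pleio_max), mean zero.
        "directional": beta2_j ~ Uniform(0, 2 * pleio_mean), so the mean is
        ``pleio_mean`` (default 0.1) and the maximum magnitude 2 * pleio_mean.
    pleio_max : float
        Maximum magnitude of balanced pleiotropic effects (grid runs use
        values up to 0.2).
    pleio_mean : float
        Mean of directional pleiotropic effects (default 0.1).
    alpha_low, alpha_high : float
        Bounds of the Uniform instrument-strength distribution.  Nonzero
        width is what gives the Egger intercept test its power.
    sigma_low, sigma_high : float
        Bounds of the Uniform outcome-SE distribution.
    alpha_se : float
        SD of measurement noise added to the reported exposure
        associations; 0 (default) means NOME holds.
    include_noise : bool
        Diagnostic switch: False suppresses the eps_j outcome noise so
        that, absent pleiotropy, the ratio estimates equal beta1 exactly.
    n_sim : int
        Monte-Carlo replicates for experiment drivers.
    seed : int
        Base RNG seed; replicate substreams are spawned from it.
    level : float
        Nominal significance level for the global tests.
    """

    m: int = 25
    beta1: float = 0.05
    pleiotropy_mode: str = "none"
    pleio_max: float = 0.0
    pleio_mean: float = 0.1
    alpha_low: float = 0.05
    alpha_high: float = 0.5
    sigma_low: float = 0.05
    sigma_high: float = 0.15
    alpha_se: float = 0.0
    include_noise: bool = True
    n_sim: int = 1000
    seed: int = 0
    level: float = 0.05

    def __post_init__(self) -> None:
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValueError(
                f"pleiotropy_mode must be one of {PLEIOTROPY_MODES}, "
                f"got {self.pleiotropy_mode!r}"
            )
        if self.m < 2:
            raise ValueError("m must be at least 2")
        if self.pleio_max < 0:
            raise ValueError("pleio_max must be nonnegative")
        if self.alpha_low <= 0 or self.alpha_high < self.alpha_low:
            raise ValueError("require 0 < alpha_low <= alpha_high")
        if self.sigma_low <= 0 or self.sigma_high < self.sigma_low:
            raise ValueError("require 0 < sigma_low <= sigma_high")
        if self.alpha_se < 0:
            raise ValueError("alpha_se must be nonnegative")
        if self.n_sim < 1:
            raise ValueError("n_sim must be at least 1")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must lie strictly between 0 and 1")

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SimulationTruth:
    """The generating parameters behind one simulated dataset."""

    beta1: float
    beta2: np.ndarray
    alpha_true: np.ndarray


def _draw_pleiotropy(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.pleiotropy_mode == "none" or (
        config.pleiotropy_mode == "balanced" and config.pleio_max == 0.0
    ):
        return np.zeros(config.m)
    if config.pleiotropy_mode == "balanced":
        return rng.uniform(-config.pleio_max, config.pleio_max, config.m)
    return rng.uniform(0.0, 2.0 * config.pleio_mean, config.m)


def simulate_summary_data(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[SummaryDataSet, SimulationTruth]:
    """Draw one summary-level dataset and its generating truth."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    alpha = rng.uniform(config.alpha_low, config.alpha_high, config.m)
    sigma = rng.uniform(config.sigma_low, config.sigma_high, config.m)
    beta2 = _draw_pleiotropy(config, rng)
    eps = rng.normal(0.0, sigma) if config.include_noise else np.zeros(config.m)
    beta_out = config.beta1 * alpha + beta2 + eps

    alpha_reported = alpha
    alpha_se = None
    if config.alpha_se > 0:
        alpha_reported = alpha + rng.normal(0.0, config.alpha_se, config.m)
        alpha_se = np.full(config.m, config.alpha_se)

    width = len(str(config.m))
    data = SummaryDataSet(
        snp_id=np.array([f"snp_{j + 1:0{width}d}" for j in range(config.m)]),
        alpha=alpha_reported,
        beta_out=beta_out,
        sigma_out=sigma,
        alpha_se=alpha_se,
    )
    return data, SimulationTruth(beta1=config.beta1, beta2=beta2, alpha_true=alpha)


@dataclass(frozen=True)
class IndividualData:
    """Two disjoint cohorts drawn from the same population.

    Cohort 1 supplies the SNP-outcome associations, cohort 2 the
    SNP-exposure associations (the two-sample design).
    """

    genotypes_1: np.ndarray
    exposure_1: np.ndarray
    outcome_1: np.ndarray
    genotypes_2: np.ndarray
    exposure_2: np.ndarray
    outcome_2: np.ndarray
    maf: np.ndarray


def _marginal_slopes(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-column simple OLS slope and SE of y on each genotype."""
    n = y.shape[0]
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    s_gg = np.sum(Gc**2, axis=0)
    s_gy = Gc.T @ yc
    slope = s_gy / s_gg
    rss = np.sum(yc**2) - slope * s_gy
    se = np.sqrt(rss / (n - 2) / s_gg)
    return slope, se


def summary_from_individual(G, exposure, outcome) -> SummaryDataSet:
    """Per-SNP marginal regressions of exposure and outcome on genotype.

    Computes, within a single sample, the SNP-exposure associations and
    the SNP-outcome associations with their SEs, yielding a summary
    dataset whose IVW estimate approximates the in-sample 2SLS estimate.
    """
    G = np.asarray(G, dtype=float)
    alpha, alpha_se = _marginal_slopes(G, np.asarray(exposure, dtype=float))
    beta_out, sigma_out = _marginal_slopes(G, np.asarray(outcome, dtype=float))
    m = G.shape[1]
    width = len(str(m))
    return SummaryDataSet(
        snp_id=np.array([f"snp_{j + 1:0{width}d}" for j in range(m)]),
        alpha=alpha,
        beta_out=beta_out,
        sigma_out=sigma_out,
        alpha_se=alpha_se,
    )


def simulate_individual_data(
    config: SimulationConfig,
    n: int,
    rng: np.random.Generator | None = None,
    maf_low: float = 0.1,
    maf_high: float = 0.5,
    confounder_effect: float = 0.5,
) -> tuple[IndividualData, SummaryDataSet, SimulationTruth]:
    """Draw two cohorts of size ``n`` each and derive summary statistics.

    Genotypes are biallelic counts ~ Binomial(2, maf_j); the continuous
    exposure is X = sum_j alpha_j G_j + confounder + noise and the outcome
    Y = beta1 X + sum_j beta2_j G_j + confounder + noise.  The returned
    summary dataset takes exposure associations from cohort 2 and outcome
    associations from cohort 1.
    """
    if n < 100:
        raise ValueError("n must be at least 100")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = config.m
    maf = rng.uniform(maf_low, maf_high, m)
    alpha_true = rng.uniform(config.alpha_low, config.alpha_high, m)
    beta2 = _draw_pleiotropy(config, rng)

    def _cohort():
        G = rng.binomial(2, maf, size=(n, m)).astype(float)
        u = rng.normal(0.0, 1.0, n)
        x = G @ alpha_true + confounder_effect * u + rng.normal(0.0, 1.0, n)
        y = (
            config.beta1 * x
            + G @ beta2
            + confounder_effect * u
            + rng.normal(0.0, 1.0, n)
        )
        return G, x, y

    G1, x1, y1 = _cohort()
    G2, x2, y2 = _cohort()

    alpha_hat, alpha_se = _marginal_slopes(G2, x2)
    beta_out, sigma_out = _marginal_slopes(G1, y1)
    width = len(str(m))
    summary = SummaryDataSet(
        snp_id=np.array([f"snp_{j + 1:0{width}d}" for j in range(m)]),
        alpha=alpha_hat,
        beta_out=beta_out,
        sigma_out=sigma_out,
        alpha_se=alpha_se,
    )
    individual = IndividualData(
        genotypes_1=G1, exposure_1=x1, outcome_1=y1,
        genotypes_2=G2, exposure_2=x2, outcome_2=y2, maf=maf,
    )
    truth = SimulationTruth(beta1=config.beta1, beta2=beta2, alpha_true=alpha_true)
    return individual, summary, truth


def truth_sidecar(truth: SimulationTruth, config: SimulationConfig) -> str:
    """JSON sidecar with the generating truth and a config echo."""
    return json.dumps(
        {
            "beta1": truth.beta1,
            "beta2": list(map(float, truth.beta2)),
            "alpha_true": list(map(float, truth.alpha_true)),
            "config": config.to_dict(),
        },
        indent=2,
    )
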