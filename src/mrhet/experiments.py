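"""Seeded Monte-Carlo experiment drivers.

Three studies around the heterogeneity statistics:

* a power study tracing, over a grid of balanced-pleiotropy magnitudes,
  the rejection rates of the Cochran's Q test, the Rucker's Q' test and
  the MR-Egger intercept test;
* a per-SNP contribution profile for a single directional-pleiotropy
  dataset, annotated with the uncorrected and Bonferroni chi-squared(1)
  thresholds;
* a weak-instrument study tracing the type-I error of the Q test as
  measurement error in the exposure associations grows (NOME violation).

Every driver is reproducible from (config, seed) alone: replicate
substreams are spawned deterministically from the base seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import estimators, heterogeneity
from .simulator import SimulationConfig, simulate_summary_data

__all__ = [
    "PowerCurve",
    "ContributionProfile",
    "WeakInstrumentStudy",
    "run_power_study",
    "run_contribution_profile",
    "run_weak_instrument_study",
]

TESTS = ("cochran_q", "rucker_q_prime", "egger_intercept")


def _mc_se(p: np.ndarray, n: int) -> np.ndarray:
    return np.sqrt(p * (1.0 - p) / n)


@dataclass(frozen=True)
class PowerCurve:
    """Empirical rejection rates over a pleiotropy-magnitude grid."""

    c_grid: np.ndarray
    power: dict  # test name -> rejection-rate array over the grid
    mc_se: dict  # test name -> Monte-Carlo SE array
    n_sim: int
    seed: int
    level: float
    egger_random_effects: bool

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for test in TESTS:
            for i, c in enumerate(self.c_grid):
                rows.append(
                    {
                        "c": float(c),
                        "test": test,
                        "power": float(self.power[test][i]),
                        "mc_se": float(self.mc_se[test][i]),
                        "n_sim": self.n_sim,
                        "seed": self.seed,
                    }
                )
        return pd.DataFrame(rows)

    def manifest(self) -> dict:
        return {
            "experiment": "power_study",
            "c_grid": list(map(float, self.c_grid)),
            "n_sim": self.n_sim,
            "seed": self.seed,
            "level": self.level,
            "egger_intercept_se": "random-effects"
            if self.egger_random_effects
            else "fixed-effect",
        }


def run_power_study(
    config: SimulationConfig,
    c_grid,
    egger_random_effects: bool = False,
) -> PowerCurve:
    """Rejection rates of the three global tests over balanced pleiotropy.

    For each magnitude ``c`` in ``c_grid``, ``config.n_sim`` datasets are
    simulated with balanced pleiotropy of maximum magnitude ``c`` and each
    test is applied at ``config.level``; the recorded power is the fraction
    of replicates in which the test rejects.
    """
    c_grid = np.asarray(list(c_grid), dtype=float)
    if c_grid.size == 0:
        raise ValueError("c_grid must be non-empty")
    n_sim = config.n_sim
    level = config.level
    counts = {test: np.zeros(c_grid.size) for test in TESTS}

    root = np.random.SeedSequence(config.seed)
    for i, c in enumerate(c_grid):
        cfg = config.replace(pleiotropy_mode="balanced", pleio_max=float(c))
        q_crit = stats.chi2.ppf(1.0 - level, cfg.m - 1)
        qp_crit = stats.chi2.ppf(1.0 - level, cfg.m - 2)
        child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(i,))
        for stream in child.spawn(n_sim):
            data, _ = simulate_summary_data(cfg, np.random.default_rng(stream))
            ratios = estimators.compute_ratio_estimates(data)
            ivw = estimators.ivw_estimate(ratios)
            egger = estimators.egger_regression(
                data, random_effects=egger_random_effects
            )
            counts["cochran_q"][i] += ivw.q_stat > q_crit
            counts["rucker_q_prime"][i] += egger.q_prime > qp_crit
            counts["egger_intercept"][i] += egger.intercept_pvalue < level
    power = {t: counts[t] / n_sim for t in TESTS}
    return PowerCurve(
        c_grid=c_grid,
        power=power,
        mc_se={t: _mc_se(power[t], n_sim) for t in TESTS},
        n_sim=n_sim,
        seed=config.seed,
        level=level,
        egger_random_effects=egger_random_effects,
    )


@dataclass(frozen=True)
class ContributionProfile:
    """Per-SNP Q and Q' contributions for one dataset, with thresholds."""

    table: pd.DataFrame
    q: float
    q_pvalue: float
    q_prime: float
    q_prime_pvalue: float
    threshold_uncorrected: float
    threshold_bonferroni: float
    model_hint: str
    seed: int
    config: dict

    def manifest(self) -> dict:
        return {
            "experiment": "contribution_profile",
            "seed": self.seed,
            "config": self.config,
            "threshold_uncorrected": self.threshold_uncorrected,
            "threshold_bonferroni": self.threshold_bonferroni,
        }


def run_contribution_profile(
    config: SimulationConfig | None = None,
    fwer: float = 0.05,
    rng: np.random.Generator | None = None,
) -> ContributionProfile:
    """Per-SNP contribution table for a single simulated dataset.

    Defaults emulate directional pleiotropy (mean 0.1) over 25 SNPs, the
    regime in which the Q and Q' contributions visibly separate: SNPs can
    exceed the Bonferroni threshold on Q while no SNP does on Q'.
    """
    if config is None:
        config = SimulationConfig(pleiotropy_mode="directional")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    data, _ = simulate_summary_data(config, rng)
    ratios = estimators.compute_ratio_estimates(data)
    ivw = estimators.ivw_estimate(ratios)
    egger = estimators.egger_regression(data)
    report = heterogeneity.build_pleiotropy_report(data, ivw, egger, fwer=fwer)
    qp = heterogeneity.rucker_q(data, egger)

    table = pd.DataFrame(
        {
            "snp": data.snp_id,
            "q_contrib": ivw.q_contributions,
            "q_prime_contrib": qp.contributions,
            "flag_95": report.q_flags_uncorrected,
            "flag_bonf": report.q_flags_bonferroni,
        }
    )
    return ContributionProfile(
        table=table,
        q=float(ivw.q_stat),
        q_pvalue=float(ivw.q_pvalue),
        q_prime=qp.statistic,
        q_prime_pvalue=qp.pvalue,
        threshold_uncorrected=report.threshold_uncorrected,
        threshold_bonferroni=report.threshold_bonferroni,
        model_hint=report.model_hint,
        seed=config.seed,
        config=config.to_dict(),
    )


@dataclass(frozen=True)
class WeakInstrumentStudy:
    """Type-I error of the Q test across exposure-measurement-error levels."""

    alpha_se_grid: np.ndarray
    rejection_rate: np.ndarray
    mc_se: np.ndarray
    n_sim: int
    seed: int
    level: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alpha_se": self.alpha_se_grid,
                "rejection_rate": self.rejection_rate,
                "mc_se": self.mc_se,
                "n_sim": self.n_sim,
                "seed": self.seed,
            }
        )

    def manifest(self) -> dict:
        return {
            "experiment": "weak_instrument_study",
            "alpha_se_grid": list(map(float, self.alpha_se_grid)),
            "n_sim": self.n_sim,
            "seed": self.seed,
            "level": self.level,
        }


def run_weak_instrument_study(
    config: SimulationConfig, alpha_se_grid
) -> WeakInstrumentStudy:
    """Empirical type-I error of the Q test as instruments weaken.

    Pleiotropy is off throughout, so every rejection is a false positive.
    At ``alpha_se = 0`` (NOME holds) the rate matches the nominal level;
    as the exposure associations are measured with increasing error the
    standard inverse-variance weights become miscalibrated and the Q test
    over-rejects.
    """
    grid = np.asarray(list(alpha_se_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("alpha_se_grid must be non-empty")
    n_sim = config.n_sim
    q_crit = stats.chi2.ppf(1.0 - config.level, config.m - 1)
    rates = np.zeros(grid.size)
    root = np.random.SeedSequence(config.seed)
    for i, a_se in enumerate(grid):
        cfg = config.replace(
            pleiotropy_mode="none", pleio_max=0.0, alpha_se=float(a_se)
        )
        child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(i,))
        rejected = 0
        for stream in child.spawn(n_sim):
            data, _ = simulate_summary_data(cfg, np.random.default_rng(stream))
            ratios = estimators.compute_ratio_estimates(data)
            beta_ivw = float(
                np.sum(ratios.weight * ratios.beta_ratio) / np.sum(ratios.weight)
            )
            q = float(
                np.sum(ratios.weight * (ratios.beta_ratio - beta_ivw) ** 2)
            )
            rejected += q > q_crit
        rates[i] = rejected / n_sim
    return WeakInstrumentStudy(
        alpha_se_grid=grid,
        rejection_rate=rates,
        mc_se=_mc_se(rates, n_sim),
        n_sim=n_sim,
        seed=config.seed,
        level=config.level,
    )
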