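import numpy as np
import pytest
from scipy import stats

from mrhet.data_model import (
    ConsistencyError,
    InsufficientInstrumentsError,
    SummaryDataSet,
)
from mrhet.estimators import compute_ratio_estimates, egger_regression, ivw_estimate
from mrhet.heterogeneity import (
    HeterogeneityTest,
    build_pleiotropy_report,
    cochran_q,
    individual_pleiotropy_test,
    model_hint,
    remove_outliers_and_refit,
    rucker_q,
)
from mrhet.simulator import SimulationConfig, simulate_summary_data

from oracles import wls_normal_equations


def dataset(alpha, beta_out, sigma):
    alpha = np.asarray(alpha, float)
    return SummaryDataSet(
        snp_id=np.array([f"rs{j}" for j in range(len(alpha))]),
        alpha=alpha,
        beta_out=np.asarray(beta_out, float),
        sigma_out=np.asarray(sigma, float),
    )


def test_q_zero_under_perfect_proportionality():
    alpha = np.array([0.1, 0.2, 0.3])
    data = dataset(alpha, 0.4 * alpha, np.full(3, 0.05))
    ivw = ivw_estimate(compute_ratio_estimates(data))
    assert ivw.q_stat == pytest.approx(0.0, abs=1e-18)
    assert ivw.q_pvalue == pytest.approx(1.0)


def test_q_hand_computed_two_snp_example():
    """Two unit-weight ratios of 1 and 3: IVW 2, Q = 1 + 1 = 2 on 1 df."""
    data = dataset([1.0, 1.0], [1.0, 3.0], [1.0, 1.0])
    ratios = compute_ratio_estimates(data)
    ivw = ivw_estimate(ratios)
    assert ivw.beta_ivw == pytest.approx(2.0)
    q = cochran_q(ratios, ivw.beta_ivw)
    assert q.statistic == pytest.approx(2.0)
    assert q.df == 1
    np.testing.assert_allclose(q.contributions, [1.0, 1.0])
    assert q.pvalue == pytest.approx(stats.chi2.sf(2.0, 1))


def test_q_requires_two_snps():
    ratios = compute_ratio_estimates(dataset([0.2, 0.3], [0.1, 0.2], [0.1, 0.1]))
    with pytest.raises(InsufficientInstrumentsError):
        cochran_q(ratios.__class__(ratios.snp_id[:1], ratios.beta_ratio[:1], ratios.weight[:1]), 0.0)


def test_null_q_mean_matches_chi2_mean():
    """Under no pleiotropy with strong instruments, E[Q] = m - 1."""
    cfg = SimulationConfig(m=25, seed=61)
    qs = []
    for stream in np.random.SeedSequence(cfg.seed).spawn(500):
        data, _ = simulate_summary_data(cfg, np.random.default_rng(stream))
        qs.append(ivw_estimate(compute_ratio_estimates(data)).q_stat)
    se = np.sqrt(2.0 * 24 / 500)  # chi2(24) variance is 2*24
    assert abs(np.mean(qs) - 24.0) < 3 * se


def test_q_prime_zero_on_line_with_intercept_while_q_positive():
    alpha = np.array([0.1, 0.2, 0.3, 0.4])
    data = dataset(alpha, 0.1 + 0.5 * alpha, np.full(4, 0.05))
    ivw = ivw_estimate(compute_ratio_estimates(data))
    egger = egger_regression(data)
    qp = rucker_q(data, egger)
    assert qp.statistic == pytest.approx(0.0, abs=1e-18)
    assert ivw.q_stat > 1.0


def test_q_prime_matches_oracle_rss(make_dataset):
    data = make_dataset(m=3, seed=44)
    egger = egger_regression(data)
    qp = rucker_q(data, egger)
    sign = np.where(data.alpha < 0, -1.0, 1.0)
    _, _, rss, _, _ = wls_normal_equations(
        data.alpha * sign, data.beta_out * sign, data.sigma_out
    )
    assert qp.statistic == pytest.approx(rss, rel=1e-10)


@pytest.mark.parametrize("seed", range(8))
def test_nesting_and_exact_decomposition(make_dataset, seed):
    """Q' <= Q always; both statistics equal the sum of their contributions."""
    data = make_dataset(m=4 + seed, seed=seed)
    ivw = ivw_estimate(compute_ratio_estimates(data))
    egger = egger_regression(data)
    qp = rucker_q(data, egger)
    assert qp.statistic <= ivw.q_stat + 1e-12
    assert ivw.q_stat == pytest.approx(float(np.sum(ivw.q_contributions)), rel=1e-10)
    assert qp.statistic == pytest.approx(float(np.sum(qp.contributions)), rel=1e-10)


def test_rucker_q_rejects_mismatched_fit(make_dataset):
    egger = egger_regression(make_dataset(m=6, seed=1))
    other = make_dataset(m=6, seed=2)
    with pytest.raises(ConsistencyError):
        rucker_q(other, egger)
    smaller = make_dataset(m=5, seed=3)
    with pytest.raises(ConsistencyError):
        rucker_q(smaller, egger)


def test_statistics_invariant_to_snp_order(make_dataset, rng):
    data = make_dataset(m=9, seed=77)
    perm = rng.permutation(9)
    shuffled = data.subset(perm)
    a = ivw_estimate(compute_ratio_estimates(data))
    b = ivw_estimate(compute_ratio_estimates(shuffled))
    assert b.beta_ivw == pytest.approx(a.beta_ivw, rel=1e-12)
    assert b.q_stat == pytest.approx(a.q_stat, rel=1e-10)
    ea, eb = egger_regression(data), egger_regression(shuffled)
    assert eb.q_prime == pytest.approx(ea.q_prime, rel=1e-10)
    assert eb.intercept == pytest.approx(ea.intercept, rel=1e-10)


def test_q_agrees_with_sargan_overidentification_statistic():
    """On large-n individual-level data with no pleiotropy and a small
    causal effect, Q computed from within-sample summary statistics tracks
    the classical overidentification (Sargan) statistic."""
    from mrhet.estimators import two_stage_least_squares
    from mrhet.simulator import simulate_individual_data, summary_from_individual
    from oracles import sargan_statistic

    cfg = SimulationConfig(m=25, beta1=0.05, seed=99)
    indiv, _, _ = simulate_individual_data(cfg, 20_000, np.random.default_rng(cfg.seed))
    G, x, y = indiv.genotypes_1, indiv.exposure_1, indiv.outcome_1
    summary = summary_from_individual(G, x, y)
    ivw = ivw_estimate(compute_ratio_estimates(summary))
    tsls = two_stage_least_squares(G, x, y)
    sargan = sargan_statistic(G, x, y, tsls.estimate)
    assert ivw.q_stat == pytest.approx(sargan, rel=0.1)


class TestIndividualFlags:
    def test_bonferroni_threshold_for_25_snps_is_99_8th_percentile(self):
        flags = individual_pleiotropy_test(np.zeros(25), m=25, fwer=0.05)
        assert flags.threshold_uncorrected == pytest.approx(stats.chi2.ppf(0.95, 1))
        assert flags.threshold_bonferroni == pytest.approx(stats.chi2.ppf(0.998, 1))

    def test_zero_contributions_raise_no_flags(self):
        flags = individual_pleiotropy_test(np.zeros(10), fwer=0.05)
        assert not flags.flag_uncorrected.any()
        assert not flags.flag_bonferroni.any()
        assert flags.outlier_index.size == 0

    def test_intermediate_value_flags_uncorrected_only(self):
        contrib = np.zeros(25)
        contrib[3] = stats.chi2.ppf(0.997, 1)  # above 95th, below 99.8th
        flags = individual_pleiotropy_test(contrib, m=25, fwer=0.05)
        assert flags.flag_uncorrected[3] and not flags.flag_bonferroni[3]

    def test_bonferroni_flags_are_subset_of_uncorrected(self, rng):
        contrib = rng.chisquare(1, 40) * rng.uniform(0.5, 4, 40)
        flags = individual_pleiotropy_test(contrib, fwer=0.05)
        assert not np.any(flags.flag_bonferroni & ~flags.flag_uncorrected)

    def test_invalid_fwer_rejected(self):
        with pytest.raises(ValueError):
            individual_pleiotropy_test(np.zeros(5), fwer=1.5)


class TestModelHint:
    @staticmethod
    def _het(name, stat, contributions):
        contributions = np.asarray(contributions, float)
        df = len(contributions) - 1
        return HeterogeneityTest(name, stat, df, float(stats.chi2.sf(stat, df)), contributions)

    def test_equal_statistics_give_neutral_zero_difference(self):
        contrib = np.full(5, 0.2)
        q = self._het("q", 1.0, contrib)
        flags = individual_pleiotropy_test(contrib, fwer=0.05)
        hint, diff = model_hint(q, q, flags, flags)
        assert hint == "neutral" and diff == 0.0

    def test_q_outlier_without_q_prime_outlier_hints_egger(self):
        q_contrib = np.array([0.1, 0.2, 15.0, 0.3, 0.2])
        qp_contrib = np.full(5, 0.2)
        q = self._het("q", float(q_contrib.sum()), q_contrib)
        qp = self._het("qp", float(qp_contrib.sum()), qp_contrib)
        hint, diff = model_hint(
            q, qp,
            individual_pleiotropy_test(q_contrib, fwer=0.05),
            individual_pleiotropy_test(qp_contrib, fwer=0.05),
        )
        assert hint == "egger-better"
        assert diff == pytest.approx(q.statistic - qp.statistic)

    def test_all_quiet_is_neutral(self):
        contrib = np.full(6, 0.1)
        q = self._het("q", 0.6, contrib)
        flags = individual_pleiotropy_test(contrib, fwer=0.05)
        assert model_hint(q, q, flags, flags)[0] == "neutral"


class TestOutlierRemoval:
    def test_no_outliers_is_a_fixed_point(self):
        cfg = SimulationConfig(m=10, seed=8)
        data, _ = simulate_summary_data(cfg, np.random.default_rng(3))
        ivw = ivw_estimate(compute_ratio_estimates(data))
        egger = egger_regression(data)
        report = build_pleiotropy_report(data, ivw, egger)
        assert not report.outlier_ids
        result = remove_outliers_and_refit(data, report)
        assert result.data.m == data.m
        assert result.removed_ids == []
        assert result.ivw.beta_ivw == pytest.approx(ivw.beta_ivw)
        assert result.rounds == 0

    def test_planted_outlier_is_removed_and_fit_improves(self):
        cfg = SimulationConfig(m=25, seed=15, beta1=0.05)
        data, truth = simulate_summary_data(cfg, np.random.default_rng(15))
        beta_out = data.beta_out.copy()
        beta_out[7] += 1.0  # gross pleiotropic effect on one SNP
        spiked = SummaryDataSet(data.snp_id, data.alpha, beta_out, data.sigma_out)
        ivw = ivw_estimate(compute_ratio_estimates(spiked))
        egger = egger_regression(spiked)
        report = build_pleiotropy_report(spiked, ivw, egger)
        assert spiked.snp_id[7] in report.outlier_ids
        result = remove_outliers_and_refit(spiked, report)
        assert spiked.snp_id[7] not in result.data.snp_id
        assert abs(result.ivw.beta_ivw - truth.beta1) < abs(ivw.beta_ivw - truth.beta1)

    def test_refuses_when_too_few_would_remain(self):
        # two gross outliers among three SNPs: removal would leave one
        data = dataset([1.0, 1.2, 0.8], [0.05, 5.0, -5.0], [0.01, 1.0, 1.0])
        ivw = ivw_estimate(compute_ratio_estimates(data))
        egger = egger_regression(data)
        report = build_pleiotropy_report(data, ivw, egger)
        assert len(report.outlier_ids) == 2
        with pytest.raises(InsufficientInstrumentsError, match="refusing"):
            remove_outliers_and_refit(data, report)

    def test_iterate_policy_warns_and_terminates(self, caplog):
        cfg = SimulationConfig(m=25, seed=23)
        data, _ = simulate_summary_data(cfg, np.random.default_rng(23))
        beta_out = data.beta_out.copy()
        beta_out[2] += 1.0
        beta_out[11] -= 0.6
        spiked = SummaryDataSet(data.snp_id, data.alpha, beta_out, data.sigma_out)
        ivw = ivw_estimate(compute_ratio_estimates(spiked))
        report = build_pleiotropy_report(spiked, ivw, egger_regression(spiked))
        import logging

        with caplog.at_level(logging.WARNING, logger="mrhet.heterogeneity"):
            result = remove_outliers_and_refit(spiked, report, policy="iterate")
        assert any("FWER" in rec.message for rec in caplog.records)
        assert not result.report.outlier_ids or result.data.m == 3
        assert result.data.m >= 3

    def test_unknown_policy_rejected(self, make_dataset):
        data = make_dataset(m=5, seed=2)
        ivw = ivw_estimate(compute_ratio_estimates(data))
        report = build_pleiotropy_report(data, ivw, egger_regression(data))
        with pytest.raises(ValueError):
            remove_outliers_and_refit(data, report, policy="always")
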