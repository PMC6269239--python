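"""Per-SNP outlier detection and removal-with-refit.

Simulates a null dataset, plants one grossly pleiotropic SNP, and shows
how its Q contribution crosses the Bonferroni chi-squared(1) threshold,
how removal is logged, and how the refitted IVW estimate moves back
toward the true causal effect.
"""

import numpy as np

from mrhet import SimulationConfig, analyze, simulate_summary_data
from mrhet.data_model import SummaryDataSet

config = SimulationConfig(m=25, beta1=0.05, seed=15)
data, truth = simulate_summary_data(config)

beta_out = data.beta_out.copy()
beta_out[7] += 1.0  # plant a large direct (pleiotropic) effect on one SNP
spiked = SummaryDataSet(data.snp_id, data.alpha, beta_out, data.sigma_out)

result = analyze(spiked, remove_outliers=True)
report = result.report

print(f"Bonferroni chi2(1) threshold: {report.threshold_bonferroni:.3f}")
print(f"flagged outliers: {report.outlier_ids}")
print(f"IVW before removal: {result.ivw.beta_ivw:+.4f}")
print(f"IVW after removal:  {result.removal.ivw.beta_ivw:+.4f}")
print(f"true causal effect: {truth.beta1:+.4f}")
print()
print(
    "The planted SNP dominates Q; removing it (single-pass policy) pulls\n"
    "the pooled estimate back toward the truth."
)
assert np.isclose(result.removal.ivw.beta_ivw, truth.beta1, atol=0.05)
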