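"""Type-I-error inflation of the Q test under weak instruments.

When the SNP-exposure associations are measured with error (the NOME
assumption fails), the standard inverse-variance weights ignore the
variance term beta1^2 * alpha_se^2 and Cochran's Q over-rejects even
with no pleiotropy at all.  The inflation scales with the causal effect,
so this demonstration uses beta1 = 0.5.
"""

from mrhet import SimulationConfig, run_weak_instrument_study

config = SimulationConfig(m=25, beta1=0.5, n_sim=1000, seed=9)
study = run_weak_instrument_study(config, [0.0, 0.05, 0.1, 0.15])
print(study.to_frame().to_string(index=False))
print()
print(
    "At alpha_se = 0 (strong instruments) the empirical rejection rate\n"
    "matches the nominal 5%; as measurement error grows the Q test's\n"
    "type-I error inflates grossly — rejections here are false alarms,\n"
    "not pleiotropy."
)
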