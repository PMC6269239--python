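"""Monte-Carlo power of the three global pleiotropy tests.

For balanced pleiotropy of growing maximum magnitude c, compares the
rejection rates of Cochran's Q, Rucker's Q' and the MR-Egger intercept
test at the 5% level (300 replicates per grid point keeps this quick;
increase n_sim for smoother curves).
"""

from mrhet import SimulationConfig, run_power_study

config = SimulationConfig(m=25, n_sim=300, seed=42)
curve = run_power_study(config, [0.0, 0.05, 0.1, 0.15, 0.2])
print(curve.to_frame().to_string(index=False))
print()
print(
    "Power of Q and Q' rises sharply with the pleiotropy magnitude, while\n"
    "the Egger intercept test (a test of *directional* pleiotropy, driven\n"
    "by instrument-strength variability) gains power only slowly: it was\n"
    "never meant as a global pleiotropy test.  At c=0 each test shows its\n"
    "type-I error, which should sit near the nominal 5%."
)
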