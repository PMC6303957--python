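# SYNTHETIC illustration config: the relation between LDL cholesterol (exposure)
# and systolic blood pressure (outcome), with body-mass index as the measured
# confounder and blood glucose level as the unmeasured one.
#
# The mean vector and covariance matrix below are SYNTHETIC stand-ins with
# plausible clinical magnitudes (SBP in mmHg, LDL in mmol/l, BMI in kg/m^2,
# BGL in mmol/l); they are NOT estimates from any patient cohort.  Draw a
# dataset with priorconf.generate_from_covariance(mean, cov, n, seed,
# columns=roles) and fit with `priorconf fit --intercept`.
#
# The two prior configurations mirror the two documented analysis styles:
# a high-precision prior centred on an internally estimated BMI-SBP
# coefficient, and a lower-precision prior centred on a literature value.

roles: [u, z, x, y]          # bgl, bmi, ldl, sbp
variables: [bgl, bmi, ldl, sbp]
mean: [6.5, 27.0, 3.2, 140.0]
covariance:
  - [4.0,  2.8,  0.3,  10.0]
  - [2.8, 16.0,  0.4,  24.0]
  - [0.3,  0.4,  1.0,   2.4]
  - [10.0, 24.0, 2.4, 400.0]
n: 1000

priors:
  internal_estimate:
    mu_yz: 0.32        # BMI-SBP coefficient, mmHg per kg/m^2
    tau_yz: 1000       # precision ~ sample size: strong belief
  literature_value:
    mu_yz: 0.77
    tau_yz: 100        # weaker belief in the external estimate
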