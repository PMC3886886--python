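# SISa default rates (1/day) and size parameterization.
#
# These are calibration data reconstructed from the published
# constraints rather than code: the spontaneous-infection rate and the
# normalizer reproduce the inactive-state escape times 1/(N*a) = 200,
# 286 and 500 days at network sizes 0.25, 0.175 and 0.1; the recovery
# rate is fixed by requiring the macroscopic endemic fixed point to be
# 0.4719; the transmission rate is then pinned by requiring the
# stationary ground-state reallocation (critical network size) to fall
# at 0.175.
spontaneous_infection: 1.0e-4
transmission: 0.107
recovery: 0.0566186093028184
N0: 200
omega: 1.0
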