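# Neural-network default rates (1/ms) and size parameterization.
#
# Calibration data, not code: two equal populations of excitatory and
# inhibitory neurons with tanh_plus response, constant deactivation, and
# a small activation leak that keeps the chain irreducible.  The nearly
# balanced, slightly net-excitatory coupling (w_E - w_I close to the
# deactivation rate, i.e. branching ratio near one) together with the
# default network size 0.17 (34 neurons) reproduces the published
# size-duration scaling of binned avalanches (slope ~1.43 with 4 ms
# bins) in long Gillespie records.
w_excitatory: 1.0
w_inhibitory: 0.9
external_input: 1.0e-4
deactivation: 0.1
activation_leak: 1.0e-4
ei_ratio: [1, 1]
response: tanh_plus
N0: 200
omega: 0.17
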