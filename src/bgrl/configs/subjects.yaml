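# Group-level subject parameters: serotonergic modulation coefficients on the
# three MSN pools (alpha_d1, alpha_d2, alpha_d1d2), the dopamine-availability
# clamp delta_lim (PD groups) and the medication constant delta_med (ON
# medication groups).  Learning rates are shared across groups.
HC:           {alpha_d1: 1.0, alpha_d2: 0.185, alpha_d1d2: 0.997, delta_lim: null,  delta_med: null}
PD-OFF:       {alpha_d1: 1.0, alpha_d2: 0.991, alpha_d1d2: 0.033, delta_lim: 0.001, delta_med: null}
PD-ON-ICD:    {alpha_d1: 1.0, alpha_d2: 0.046, alpha_d1d2: 0.001, delta_lim: 0.001, delta_med: 0.06}
PD-ON-nonICD: {alpha_d1: 1.0, alpha_d2: 0.916, alpha_d1d2: 0.160, delta_lim: 0.001, delta_med: 0.06}
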