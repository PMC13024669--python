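"""Physical constants used throughout mbovs."""

#: Reduced gyromagnetic ratio of 1H, gamma-bar = gamma / (2 pi), in MHz/T.
GAMMA_BAR_MHZ_PER_T = 42.577

#: Same constant in Hz/uT (1 MHz/T == 1 Hz/uT); convenient because RF
#: amplitudes are carried in uT and gradients in uT/m, so
#: ``GAMMA_BAR_HZ_PER_UT * B1[uT]`` is a nutation frequency in Hz and
#: ``GAMMA_BAR_HZ_PER_UT * Gr[uT/m] * z[m]`` a gradient-induced offset in Hz.
GAMMA_BAR_HZ_PER_UT = GAMMA_BAR_MHZ_PER_T
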