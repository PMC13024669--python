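# Slab-profile comparison across the pulse catalog (written by `characterize`).
characterize:
  pulse: am_sinc_8
  ovs: mbovs
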