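# Residual stop-band signal vs tissue T1 for the interleaved CINE protocol.
characterize:
  pulse: am_sinc_8
  ovs: mbovs
  t1_min: 0.2
  t1_max: 0.35
  t1_step: 0.025
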