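# Pulse-catalog design run: per-pulse multiband waveforms + design table.
design:
  thickness: 0.15
  flip: 90.0
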