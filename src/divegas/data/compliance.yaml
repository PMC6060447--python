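# Structural (compliance) parameters of the respiratory system.
# "updated_dolphin": fits from bottlenose dolphin compliance measurements
# (stiffer conducting airways, more compliant alveolar space).
# "legacy": earlier multi-species estimates, shipped as printed.
updated_dolphin:
  a: 1.05
  b: 0.90
  c: 2.51
  kp: -31.0
  n: 2.4
legacy:
  a: 1.1
  b: 1.2
  c: 1.3
  kp: -12.8
  n: 0.91
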