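# Lorenz-63 from clean data on [0, 20] at dt = 1e-2, fitted in conditioning
# coordinates (states / 8, z additionally shifted by 25); the report maps the
# model back to original coordinates for comparison.
benchmark:
  name: lorenz
  dt: 1.0e-2
  tf: 20.0
preprocess:
  normalize:
    scale: [8.0, 8.0, 8.0]
    shift: [0.0, 0.0, 25.0]
dictionary:
  degree: 3
fit:
  cutoff: 0.5
seed: 0
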