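# FitzHugh-Nagumo neuron model from clean data on [0, 600] s at dt = 0.1,
# degree-3 dictionary, fixed cut-off thresholding.
benchmark:
  name: fhn
  dt: 0.1
  tf: 600.0
dictionary:
  degree: 3
fit:
  cutoff: 1.0e-2
seed: 0
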