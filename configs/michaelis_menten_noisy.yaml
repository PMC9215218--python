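# Rational enzyme-kinetics discovery from noise-corrupted substrate data:
# sigma = 2e-2 Gaussian noise, Savitzky-Golay denoising, standardization,
# degree-4 numerator/denominator dictionaries; front points at support
# sizes <= 4 are recomputed by exact enumeration.
benchmark:
  name: michaelis_menten
noise:
  sigma: 2.0e-2
preprocess:
  denoise:
    window: 21
    polyorder: 3
  normalize: standard
dictionary:
  rational:
    degree_g: 4
    degree_h: 4
fit:
  alpha: 1.0e-6
  exact_size_cap: 4
seed: 0
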