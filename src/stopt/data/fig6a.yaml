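# One-parameter, one-metric demonstration: f(x) = 1 - x^2 on [-1, 1],
# target range [0.6, 0.68], m(1) = 3, Gaussian noise sd 0.05.
name: fig6a
parameters:
  x: {domain: [-1.0, 1.0]}
metrics:
  f: {target: [0.6, 0.68]}
dependencies:
  x: [f]
optimizer:
  m: {1: 3}
  max_depth: 5
  replicates: 100
  max_processes: 1
  seed: 1
evaluator:
  type: synthetic
  landscape: fig6a
  noise_sd: 0.05
output: stopt_output/fig6a
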