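# Default end-to-end pipeline config: synthesize the Nepal rice survey,
# summarize it, simulate exposure for the bundled population groups and
# characterize risk. `dietrisk run --config <this file> --out <dir>`.
data:
  synthetic: default
tox: default
groups: default
elements: [Cd, As, Pb, Cu]
iterations: 10000
seed: 42
mode: fitted
levels: [50, 75, 90, 95, 97.5, 99, 99.9]
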