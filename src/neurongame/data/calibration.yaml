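# Calibration profile v3: produced by the grid-search harness
# (neurongame.calibration.grid_search) scoring reduced-session group
# statistics (success rate, correct-response rate; decoding error and the
# cooperation measure as tie-breakers) against the published model-level
# statistics. The Bayes and Thompson units share one belief pipeline and
# therefore one block of values.
profile: v3
models:
  bayes:
    beta1: 0.35
    beta2: 0.01
    beta3: 0.05
    gain: 20.0
    q: 0.1939
    epsilon_base: 0.85
  thompson:
    beta1: 0.35
    beta2: 0.01
    beta3: 0.05
    gain: 20.0
    q: 0.1939
    epsilon_base: 0.85
  rl:
    beta1: 0.9
    beta2: 0.05
    beta3: 0.01
    gain: 20.0
    q: 0.1939
    epsilon_base: 0.85
    alpha: 0.035
    gamma: 0.9
    lam: 0.5
  ann:
    beta1: 0.9
    beta2: 0.05
    beta3: 0.1
    gain: 5.0
    q: 0.1939
    epsilon_base: 0.85
    alpha: 0.007
    variant: feature_based
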