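# Demo pipeline: small synthetic dataset through every stage (< 5 min, 1 CPU).
stages: [synth, analytics, dwell, sim]
geometry: null
synth:
  eb1:
    n_comets: 400
    # long-lived comets so the dwell stage sees plenty of cortex contacts
    hazard_far: 0.02
    hazard_near: 0.02
  oskar:
    n_particles: 400
analytics: {}
dwell: {}
sim:
  mode: static
  static:
    epsilon: 0.5
    n_mts: 150
    n_cargo: 150
    T_total: 600.0
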