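# End-to-end demo: simulate a small latent-state dataset, then run every
# analysis stage on it.  `statesync run --config demo_pipeline.yaml --out out/`
# is fully deterministic: running it twice produces byte-identical outputs.
seed: 7
stages:
  - name: simulate
    params:
      n_subjects: 8
      T: 200
      V: 40
      k: 4
      noise_sd: 1.0
      ar1_rho: 0.3
      event_windows: [[80, 110, 2]]
  - name: isc
    params:
      mode: temporal
      n_boot: 200
  - name: autocorr
    params:
      max_lag: 30
      threshold: 0.1
  - name: hmm
    params:
      mode: group
      k: 4
  - name: concordance
    params:
      k: 4
  - name: srm
    params:
      d: 5
  - name: cf
    params:
      width_s: 60
      n_factors: 2
      n_iter: 50
      simulate:
        n_subjects: 15
        duration_s: 600
        rank: 2
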