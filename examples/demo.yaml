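# Demonstration history: a two-source island population founded 20 generations
# ago by source-1 females and a limited stock of source-2 males (40 founders),
# with continued female-only source-1 immigration (10% of mothers per
# generation) and ancestry-assortative mating (target spousal correlation 0.4).
seed: 20260928
simulate:
  N: 500
  G: 20
  rho: 0.4
  n_founders: 40
  map:
    autosomes_mb: [60.0, 58.3, 56.7, 55.0, 53.3, 51.7, 50.0, 48.3, 46.7, 45.0,
                   43.3, 41.7, 40.0, 38.3, 36.7, 35.0, 33.3, 31.7, 30.0, 28.3,
                   26.7, 25.0]
    x_mb: 50.0
  schedule:
    kind: constant
    s1f: 0.1
    s1m: 0.0
    s2f: 0.0
    s2m: 0.0
    founding_s1f: 1.0
    founding_s1m: 0.0
params:
  B: 1000
  ibd_subsample: 60
  roh_scheme: fixed
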