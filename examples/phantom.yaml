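# A small phantom for quick CLI runs: 3 B-scans of 200 A-scans, 160 depth
# pixels, standard physical spacings, study-level noise.
phantom:
  geometry:
    n_bscans: 3
    n_ascans: 200
    n_depth: 160
  inner_surface_um: 120.0
  noise_sigma: 0.05
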