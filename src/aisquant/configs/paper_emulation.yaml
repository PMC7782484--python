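# Bundled emulation run: long-term deprivation cohorts (P15) plus the
# paired enriched-environment hemisphere design, on synthetic data.
seed: 0
theta: 0.20
window_um: 1.0
pixel_size_um: 0.21
psf_sigma_um: 0.5
noise_sd: 0.1
measure_profiles: true
cohorts:
  P15-Ctrl: {preset: P15-Ctrl, n_animals: 6, n_per_animal: 100}
  P15-Dep: {preset: P15-Dep, n_animals: 6, n_per_animal: 100}
comparisons:
  - [P15-Ctrl, P15-Dep]
paired:
  - {name: EE-3h, ctrl: EE-Ctrl-3h, stim: EE-Stim-3h, n_animals: 6, n_per_hemisphere: 100}
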