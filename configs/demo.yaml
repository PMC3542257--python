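seed: 0
lvs_fraction: 0.4
lfdr_max: 0.1
amplitude_min: 1.6
grid: 1.0:4.0:0.05
bandwidth: 0.5
bh_q: 0.05
slope_min: 0.0001
uniform_cutoff: 1.5
var_floor: 1.0e-08
probes: null
annotation: null
annotation_sidecar: null
design: null
categories: null
simulation:
  n_coding: 300
  n_ncrna: 30
  genome_length: 450000
  resolution: 22
  replicates: 2
  category_scheme:
    prophage: 0.05
    iron: 0.05
    translation: 0.1
    stress: 0.1
  effects:
    frac_direct_up: 0.2
    frac_indirect_down: 0.06
    up_log2_mean: 1.6
    up_log2_sd: 0.6
    down_log2_mean: -1.0
    down_log2_sd: 0.4
    noise_sd_probe_affinity: 0.25
    noise_sd_replicate: 0.1
    saturation_ceiling: 16.0
    baseline_mean: 10.0
    baseline_sd: 1.5
    background_mean: 4.0
    array_slope_sd: 0.02
    array_offset_sd: 0.1
    seed: 0
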