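# Bundled demo: three genotype-like conditions whose injected abnormal-event
# probabilities mirror a low / intermediate / high arrhythmic burden
# (roughly 1%, 5% and 11% of transients), six scans each.
seed: 0
n_scans_per_condition: 6
conditions:
  wildtype:
    p_double_peak: 0.005
    p_small_amplitude: 0.005
  heterozygous:
    p_double_peak: 0.025
    p_small_amplitude: 0.025
  homozygous:
    p_double_peak: 0.055
    p_small_amplitude: 0.055
sim:
  duration_s: 300.0
  line_period_s: 0.075
  beat_rate_hz: 0.4
  amplitude: 100.0
  f0: 100.0
  bleach_tau_s: 600.0
  noise_sd: 5.0
baseline:
  kind: exponential
  window_s: 10.0
  percentile: 10.0
detection:
  prominence_frac: 0.2
  min_interval_s: 0.3
  return_tolerance_frac: 0.25
classification:
  ratio_threshold: 0.75
summary_mode: per_scan
stats:
  method: kruskal_dunn
  control: wildtype
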