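# Calibrated AIS cohort configuration (generator defaults).
# Loading this file reproduces CohortConfig(group="ais") exactly; edit a copy
# to explore other cohorts.
group: ais
n_subjects: 77
pattern_probs: [0.69, 0.08, 0.23]  # primary thoracic / primary (thoraco)lumbar / double
standing_cobb_t:
  thoracic: [65.2, 16.0]
  lumbar: [43.5, 14.0]
  double: [66.3, 16.0]
ct_cobb_gain: 0.92
ct_cobb_noise_sd: 4.0
rot_per_standing_deg: 0.5      # 5 degrees of apex rotation per 10 degrees standing Cobb
rot_noise_sd: 2.6
rot_t_mean: 24.0
dap_per_standing_deg: 0.12     # 1.2% anterior excess per 10 degrees standing Cobb
dap_noise_sd: 1.87
dap_t_mean: 3.8
cobb_l:
  thoracic: [28.0, 10.0]
  lumbar: [57.0, 12.0]
  double: [55.0, 12.0]
rot_l:
  thoracic: [-4.0, 5.0]
  lumbar: [-20.0, 6.0]
  double: [-19.0, 8.0]
rot_l_mean: -9.0
dap_l:
  thoracic: [8.6, 2.2]
  lumbar: [10.8, 2.3]
  double: [11.4, 2.2]
dap_l_mean: 9.4
apical_thoracic: [7.1, 4.8]
apical_lumbar: [11.2, 4.1]
proximal_junctional: [-1.3, 4.7]
distal_junctional: [1.0, 2.7]
junctional_margin: 0.85
wedge_noise_deg: 0.05
twist_noise_deg: 0.1
observer_jitter_mm: 0.05
moment_match: true
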