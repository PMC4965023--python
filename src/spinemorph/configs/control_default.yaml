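# Calibrated control cohort configuration (generator defaults).
group: control
n_subjects: 22
control_thoracic: [-4.1, 1.8]  # T4-T12 anterior excess (%): physiological kyphosis
control_lumbar: [7.8, 3.6]     # L1-L5 anterior excess (%): physiological lordosis
wedge_noise_deg: 0.05
control_twist_noise_deg: 0.2
observer_jitter_mm: 0.05
moment_match: true
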