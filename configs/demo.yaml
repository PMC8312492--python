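# Demo configuration: study-standard thresholds, reduced permutation count
# so the full chain finishes quickly on one CPU.
mmm_offset: 1.0
dhw_window_days: 84
wind_thr: 4.0
rain_thr: 50.0
wave_thr: 150.0
min_prevalence: 0.05
n_perm: 999
seed: 0
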