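{
  "fixation_offset_mean": [0.0, 0.32],
  "fixation_offset_sd": [0.40, 0.75],
  "fixation_jitter_sd": 0.30,
  "pursuit_offset_mean": 0.15,
  "pursuit_offset_sd": 0.34,
  "pursuit_hgain_mean": 1.02,
  "pursuit_hgain_sd": 0.04,
  "pursuit_vgain_mean": 1.02,
  "pursuit_vgain_sd": 0.04,
  "pursuit_catchup_rate": 1.05,
  "vor_bcea_mean": 3.98,
  "vor_bcea_sd": 0.90,
  "vor_gain_mean": 0.95,
  "vor_gain_sd": 0.04,
  "vor_saccade_rate": 0.8,
  "prosaccade_latency_mean": 0.28,
  "prosaccade_latency_sd": 0.05,
  "antisaccade_latency_mean": 0.31,
  "antisaccade_latency_sd": 0.06,
  "prosaccade_correct_p": 0.92,
  "antisaccade_correct_p": 0.76,
  "stroop_latency_mean": 0.55,
  "stroop_latency_sd": 0.12,
  "stroop_correct_p1": 0.75,
  "stroop_correct_p2": 0.70,
  "ego_offset_mean": 1.6,
  "ego_offset_sd": 0.7,
  "ego_time_mean": 1.9,
  "ego_time_sd": 0.5
}
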