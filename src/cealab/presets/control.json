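{
  "fixation_offset_mean": [0.0, -0.29],
  "fixation_offset_sd": [0.40, 0.47],
  "fixation_jitter_sd": 0.25,
  "pursuit_offset_mean": 0.003,
  "pursuit_offset_sd": 0.26,
  "pursuit_hgain_mean": 1.03,
  "pursuit_hgain_sd": 0.03,
  "pursuit_vgain_mean": 1.03,
  "pursuit_vgain_sd": 0.03,
  "pursuit_catchup_rate": 0.50,
  "vor_bcea_mean": 3.26,
  "vor_bcea_sd": 0.94,
  "vor_gain_mean": 0.98,
  "vor_gain_sd": 0.02,
  "vor_saccade_rate": 0.4,
  "prosaccade_latency_mean": 0.25,
  "prosaccade_latency_sd": 0.04,
  "antisaccade_latency_mean": 0.28,
  "antisaccade_latency_sd": 0.05,
  "prosaccade_correct_p": 0.97,
  "antisaccade_correct_p": 0.85,
  "stroop_latency_mean": 0.45,
  "stroop_latency_sd": 0.10,
  "stroop_correct_p1": 0.85,
  "stroop_correct_p2": 0.80,
  "ego_offset_mean": 1.0,
  "ego_offset_sd": 0.5,
  "ego_time_mean": 1.5,
  "ego_time_sd": 0.4
}
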