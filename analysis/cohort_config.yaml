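# Study-style cohort: delay fear conditioning (7 CS-US pairings, 35
# unreinforced CS+ extinction trials in five blocks of seven), a control
# group and a cerebellar-inactivation-like group.  LFP is generated at
# 250 Hz here to keep session dumps light; the ERP band (1-32 Hz) is
# unaffected.
protocol:
  paradigm: delay
  n_acquisition_trials: 7
  n_extinction_trials: 35
  block_size: 7
  iti_range_s: [60.0, 120.0]

groups:
  - name: control
    condition: control
    n_sessions: 6
    units:
      - {template: type1_both, count: 2, onset_gain: 6.0, offset_gain: 6.0}
      - {template: type1_onset, count: 1, onset_gain: 6.0}
      - {template: type2, count: 2}
      - {template: type4_onset_dec, count: 1, onset_gain: 0.15, response_width_s: 0.4}
    behavior: {}
    lfp: {n_channels: 4, sample_rate_hz: 250.0}
    cluster:
      cluster_means: [[0, 0, 0, 0], [25, 0, 0, 0], [0, 25, 0, 0],
                      [0, 0, 25, 0], [0, 0, 0, 25], [18, 18, 0, 0]]
      cluster_sizes: [60, 60, 60, 60, 60, 60]
      n_noise_spikes: 80

  - name: muscimol
    condition: muscimol_like
    n_sessions: 4
    units:
      # inactivation-like: dispersed multi-peak offset responses; the
      # complex starts early enough that its jittered third sub-peak
      # stays inside the 500 ms window (later starts trip the late-peak
      # exclusion rule and drop the unit from peak summaries)
      - {template: type1_both, count: 3, onset_gain: 6.0, offset_gain: 6.0,
         response_latency_s: 0.02, latency_jitter_sd_s: 0.03, n_subpeaks: 3,
         response_width_s: 0.08}
      - {template: type2, count: 2}
    behavior: {epoch_duration_scale: 3.0}
    lfp: {n_channels: 4, sample_rate_hz: 250.0}
    cluster:
      cluster_means: [[0, 0, 0, 0], [25, 0, 0, 0], [0, 25, 0, 0],
                      [0, 0, 25, 0], [0, 0, 0, 25]]
      cluster_sizes: [60, 60, 60, 60, 60]
      n_noise_spikes: 80
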