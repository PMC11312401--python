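# Bundled condition presets.
#
# ph_series: cilia reactivated by 2.5 mM ATP + 10 uM 8Br-cAMP at pH 7.0-8.0.
#   target_cbf_hz / amplitude_um encode the reported cohort-mean CBF and CBD;
#   t_eff_ms / t_rec_ms / interval_mean_ms encode the reported stroke
#   durations and mean inter-beat intervals.  The two families of numbers are
#   mutually inconsistent, hence the two simulation modes (rate_matched for
#   CBF/CBD work, component_matched for stroke/interval work).  pH 7.2 t_eff
#   (90 ms) is a linear interpolation; pH 7.4 absolute CBF/CBD (8.8 Hz,
#   0.98 um) are the compromise of the values implied by the printed ratios.
# atp_series: ATP alone (no cAMP) at pH 7.4; sparse, low-amplitude beating.
#   Stroke components are not reported for this regime; t_eff/t_rec are taken
#   from the pH 7.4 row and the interval mean chosen so the component sum
#   matches the reported rate.
# representative: single-cilium examples (one recording each).
# "null": conditions with no repeated beating; amplitude 0 disables the beat
#   train and the Ornstein-Uhlenbeck baseline fluctuation stands in for the
#   sub-threshold jiggling of an unreactivated cilium.
presets:
  - label: pH7.0
    group: ph_series
    n_cilia: 4
    n_intervals: 60
    default_mode: rate_matched
    target_cbf_hz: 3.4
    amplitude_um: 0.57
    t_eff_ms: 136.0
    t_rec_ms: 38.0
    interval_mean_ms: 234.0
    interval_sigma_log: 0.45
  - label: pH7.2
    group: ph_series
    n_cilia: 4
    n_intervals: 60
    default_mode: rate_matched
    target_cbf_hz: 5.0
    amplitude_um: 0.81
    t_eff_ms: 90.0
    t_rec_ms: 38.0
    interval_mean_ms: 212.0
    interval_sigma_log: 0.45
  - label: pH7.4
    group: ph_series
    n_cilia: 11
    n_intervals: 82
    default_mode: rate_matched
    target_cbf_hz: 8.8
    amplitude_um: 0.98
    t_eff_ms: 44.0
    t_rec_ms: 38.0
    interval_mean_ms: 120.0
    interval_sigma_log: 0.45
  - label: pH7.6
    group: ph_series
    n_cilia: 6
    n_intervals: 92
    default_mode: rate_matched
    target_cbf_hz: 11.5
    amplitude_um: 1.31
    t_eff_ms: 37.0
    t_rec_ms: 38.0
    interval_mean_ms: 53.0
    interval_sigma_log: 0.45
  - label: pH7.8
    group: ph_series
    n_cilia: 6
    n_intervals: 63
    default_mode: rate_matched
    target_cbf_hz: 13.7
    amplitude_um: 1.31
    t_eff_ms: 37.0
    t_rec_ms: 38.0
    interval_mean_ms: 44.0
    interval_sigma_log: 0.45
  - label: pH8.0
    group: ph_series
    n_cilia: 4
    n_intervals: 82
    default_mode: rate_matched
    target_cbf_hz: 15.4
    amplitude_um: 1.45
    t_eff_ms: 37.0
    t_rec_ms: 38.0
    interval_mean_ms: 31.0
    interval_sigma_log: 0.45
  - label: ATP0.5
    group: atp_series
    n_cilia: 4
    default_mode: rate_matched
    target_cbf_hz: 0.69
    amplitude_um: 0.30
    t_eff_ms: 44.0
    t_rec_ms: 38.0
    interval_mean_ms: 1367.0
    interval_sigma_log: 0.45
  - label: ATP2.5
    group: atp_series
    n_cilia: 5
    default_mode: rate_matched
    target_cbf_hz: 1.44
    amplitude_um: 0.44
    t_eff_ms: 44.0
    t_rec_ms: 38.0
    interval_mean_ms: 612.0
    interval_sigma_log: 0.45
  - label: ATP7.5
    group: atp_series
    n_cilia: 5
    default_mode: rate_matched
    target_cbf_hz: 0.96
    amplitude_um: 0.36
    t_eff_ms: 44.0
    t_rec_ms: 38.0
    interval_mean_ms: 960.0
    interval_sigma_log: 0.45
  - label: ATP10
    group: atp_series
    n_cilia: 4
    default_mode: rate_matched
    target_cbf_hz: 0.40
    amplitude_um: 0.20
    t_eff_ms: 44.0
    t_rec_ms: 38.0
    interval_mean_ms: 2418.0
    interval_sigma_log: 0.45
  - label: rep_pH7.0
    group: representative
    n_cilia: 1
    default_mode: rate_matched
    target_cbf_hz: 3.0
    amplitude_um: 0.6
    t_eff_ms: 136.0
    t_rec_ms: 38.0
    interval_mean_ms: 234.0
    interval_sigma_log: 0.45
  - label: rep_pH7.4
    group: representative
    n_cilia: 1
    default_mode: rate_matched
    target_cbf_hz: 7.0
    amplitude_um: 1.0
    t_eff_ms: 44.0
    t_rec_ms: 38.0
    interval_mean_ms: 120.0
    interval_sigma_log: 0.45
  - label: rep_pH8.0
    group: representative
    n_cilia: 1
    default_mode: rate_matched
    target_cbf_hz: 12.0
    amplitude_um: 1.5
    t_eff_ms: 37.0
    t_rec_ms: 38.0
    interval_mean_ms: 31.0
    interval_sigma_log: 0.45
  - label: unstimulated
    group: "null"
    n_cilia: 5
    default_mode: component_matched
    amplitude_um: 0.0
    t_eff_ms: 44.0
    t_rec_ms: 38.0
    interval_mean_ms: 1000.0
    fluct_sd_um: 0.08
    fluct_tau_ms: 300.0
  - label: ATPgS
    group: "null"
    n_cilia: 5
    default_mode: component_matched
    amplitude_um: 0.0
    t_eff_ms: 44.0
    t_rec_ms: 38.0
    interval_mean_ms: 1000.0
    fluct_sd_um: 0.08
    fluct_tau_ms: 300.0
  - label: PKI_pre
    group: "null"
    n_cilia: 5
    default_mode: component_matched
    amplitude_um: 0.0
    t_eff_ms: 44.0
    t_rec_ms: 38.0
    interval_mean_ms: 1000.0
    fluct_sd_um: 0.08
    fluct_tau_ms: 300.0
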