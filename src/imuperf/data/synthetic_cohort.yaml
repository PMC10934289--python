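# SYNTHETIC cohort recipe — not measured data.
#
# Three latent physical-performance groups (low / intermediate / high) for an
# 84-participant older-adult cohort.  Feature means sit at the scale of
# published clinical-test values for this population (Sit-to-Stand counts
# ~8-13, peak vertical accelerations ~12-14 m/s^2, six-minute walk distances
# ~330-510 m, step durations ~0.46-0.52 s, step lengths ~0.55-0.78 m, Timed Up
# and Go times ~6-10 s).  Within-group SDs describe spread WITHIN a
# performance cluster — tighter than whole-cohort SDs, since the groups are
# meant to be separable by unsupervised clustering on raw (unstandardized)
# features, where the walk distance (in metres) dominates the Euclidean
# geometry.
groups:
  - label: LPP
    n: 22
    faller_prob: 0.4545
    frailty_probs: [0.1818, 0.4091, 0.4091]   # robust, pre-frail, frail
    female_prob: 0.68
    age_mean: 77.5
    age_sd: 4.4
    feature_means:
      sts_count: 8.0
      sts_peak_accel_mean: 11.9
      six_mwt_distance: 325.0
      step_duration_mean: 0.52
      step_length_mean: 0.55
      tug_comfort_s: 10.5
      tug_fast_s: 9.5
    feature_sds:
      sts_count: 2.5
      sts_peak_accel_mean: 1.8
      six_mwt_distance: 18.0
      step_duration_mean: 0.04
      step_length_mean: 0.07
      tug_comfort_s: 1.3
      tug_fast_s: 1.5
  - label: IPP
    n: 39
    faller_prob: 0.4103
    frailty_probs: [0.2564, 0.6410, 0.1026]
    female_prob: 0.72
    age_mean: 75.1
    age_sd: 5.6
    feature_means:
      sts_count: 11.8
      sts_peak_accel_mean: 12.5
      six_mwt_distance: 430.0
      step_duration_mean: 0.47
      step_length_mean: 0.68
      tug_comfort_s: 8.8
      tug_fast_s: 6.9
    feature_sds:
      sts_count: 2.8
      sts_peak_accel_mean: 1.8
      six_mwt_distance: 18.0
      step_duration_mean: 0.04
      step_length_mean: 0.06
      tug_comfort_s: 1.1
      tug_fast_s: 1.0
  - label: HPP
    n: 23
    faller_prob: 0.3478
    frailty_probs: [0.4348, 0.4782, 0.0870]
    female_prob: 0.65
    age_mean: 69.4
    age_sd: 4.3
    feature_means:
      sts_count: 12.4
      sts_peak_accel_mean: 14.3
      six_mwt_distance: 515.0
      step_duration_mean: 0.46
      step_length_mean: 0.78
      tug_comfort_s: 7.9
      tug_fast_s: 5.7
    feature_sds:
      sts_count: 3.0
      sts_peak_accel_mean: 1.5
      six_mwt_distance: 18.0
      step_duration_mean: 0.04
      step_length_mean: 0.06
      tug_comfort_s: 0.9
      tug_fast_s: 0.8
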