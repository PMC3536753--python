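# Shipped LPS preparation presets.
#
# Central single-cell pulse parameters and population structure for the three
# E. coli LPS sources modeled by the package.  Parameter curves are anchor
# lists [[concentration_ug_per_mL, value], ...] interpolated log-linearly in
# concentration (flat beyond the outermost anchors); scalars are constant.
#
# Anchors encode, at 0.5 ug/mL: EB amplitude = 0.49 x Sigma, EB time-to-peak
# = 3.0 x Sigma, UP amplitude = 1.17 x Sigma, UP time-to-peak = 1.45 x Sigma,
# Sigma peak width = 1.475 x EB; and the UP time-to-peak series 52 / 69 / 129
# minutes at 5 / 0.5 / 0.05 ug/mL.  Dose models place Sigma's potency window
# near 5e-4..5e-3 ug/mL, UP's near 0.5..5 ug/mL (inert at the lowest
# concentrations), and EB active across the whole nine-decade range.
schema_version: 1
presets:
  Sigma:
    dose_model: {pmax: 0.95, K: 1.0e-4, h: 1.0}
    baseline: 1.0
    amplitude: 0.9
    time_to_peak: [[5.0e-4, 60.0], [0.5, 47.5862068965517]]
    peak_width: 89.975
    heterogeneity:
      cv_amplitude: 0.25
      cv_time_to_peak: 0.25
      cv_baseline: 0.05
      class_mix: {transient: 0.5, persistent: 0.5, secondary: 0.0}
    class_effects:
      plateau_frac: 0.2
      plateau_rise: 150.0
      secondary_frac: 0.8
      secondary_delay: 180.0
      secondary_decay: 60.0
    stnfr_modifier: {persistent_prob_factor: 0.1, plateau_amp_factor: 0.2}
  EB:
    dose_model: {pmax: 0.95, K: 1.0e-8, h: 0.7}
    baseline: 1.0
    amplitude: 0.441
    time_to_peak: 142.758620689655
    peak_width: 61.0
    heterogeneity:
      cv_amplitude: 0.25
      cv_time_to_peak: 0.25
      cv_baseline: 0.05
      class_mix: {transient: 0.45, persistent: 0.15, secondary: 0.40}
    class_effects:
      plateau_frac: 0.2
      plateau_rise: 150.0
      secondary_frac: 0.8
      secondary_delay: 180.0
      secondary_decay: 60.0
    stnfr_modifier: {persistent_prob_factor: 0.1, plateau_amp_factor: 0.2}
  UP:
    dose_model: {pmax: 0.95, K: 0.15, h: 1.2}
    baseline: 1.0
    amplitude: [[0.05, 0.75], [0.5, 1.053], [5.0, 1.15]]
    time_to_peak: [[0.05, 129.0], [0.5, 69.0], [5.0, 52.0]]
    peak_width: 61.0
    heterogeneity:
      cv_amplitude: 0.25
      cv_time_to_peak: 0.25
      cv_baseline: 0.05
      class_mix: {transient: 0.8, persistent: 0.2, secondary: 0.0}
    class_effects:
      plateau_frac: 0.2
      plateau_rise: 150.0
      secondary_frac: 0.8
      secondary_delay: 180.0
      secondary_decay: 60.0
    stnfr_modifier: {persistent_prob_factor: 0.1, plateau_amp_factor: 0.2}
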