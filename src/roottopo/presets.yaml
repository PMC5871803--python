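# Genotype presets for the synthetic root-system generator.
# Lengths in cm, times in days.  `mock` is the standard parameter set;
# each of the six named genotypes changes exactly one parameter
# (growth rate: slow/fast; inter-lateral distance: dense/sparse;
# gravitropism: steep/shallow).  `fibrous` and `taproot` are the two
# root-system categories (many thin seminal axes vs one dominant axis).
mock:
  n_first_order: 1
  elongation_rate: 2.0
  inter_lateral_distance: 1.0
  insertion_angle_mean: 65.0
  insertion_angle_sd: 8.0
  gravitropism_strength: 0.12
  heading_noise_sd: 6.0
  max_order: 3
  diameter_base: 0.12
  diameter_ratio_lateral: 0.5
  duration: 18.0
  step: 0.5
slow:
  elongation_rate: 1.0
fast:
  elongation_rate: 4.0
dense:
  inter_lateral_distance: 0.5
sparse:
  inter_lateral_distance: 2.0
steep:
  gravitropism_strength: 0.35
shallow:
  gravitropism_strength: 0.01
fibrous:
  n_first_order: 6
  max_order: 2
  elongation_rate: 2.2
  inter_lateral_distance: 1.5
  gravitropism_strength: 0.06
  diameter_base: 0.08
  diameter_ratio_lateral: 0.6
  duration: 16.0
taproot:
  n_first_order: 1
  max_order: 3
  elongation_rate: 2.5
  inter_lateral_distance: 1.0
  gravitropism_strength: 0.3
  insertion_angle_mean: 60.0
  diameter_base: 0.2
  diameter_ratio_lateral: 0.45
  duration: 14.0
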