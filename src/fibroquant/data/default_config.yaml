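# Default analysis configuration.
# Hue/saturation/brightness bounds are inclusive, on the 8-bit (0-255) scale.
bins:
  red:    {h_lo: 1,  h_hi: 13,  s_lo: 10, s_hi: 255, b_lo: 20, b_hi: 255}
  orange: {h_lo: 14, h_hi: 25,  s_lo: 10, s_hi: 255, b_lo: 20, b_hi: 255}
  yellow: {h_lo: 26, h_hi: 52,  s_lo: 10, s_hi: 255, b_lo: 20, b_hi: 255}
  green:  {h_lo: 53, h_hi: 110, s_lo: 10, s_hi: 255, b_lo: 20, b_hi: 255}
blue_range: {h_lo: 121, h_hi: 179, s_lo: 20, s_hi: 255, b_lo: 10, b_hi: 255}
preprocess:
  dark_quantile: 0.25   # darkest fraction used for background estimation
  white_cut: 230        # brightness at/above which a pixel can be "empty"
  min_sat: 25           # saturation at/below which a bright pixel is "empty"
aggregation: patient    # or "core": unit over which replicates are averaged
reference_group: null   # group normalized to 1.000; must be set for comparisons
seed: 0
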