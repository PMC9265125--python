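# Canonical feature roster: the single source of truth for feature names,
# per-family counts and column order. Family counts are contractual
# (8 morphology, 18 intensity, 20 histogram, 11/13/13/16/5 texture);
# extraction refuses to run if these counts are violated.
registry_version: 1
families:
  MORPH:
    - mesh_volume
    - voxel_volume
    - surface_area
    - surface_to_volume_ratio
    - sphericity
    - compactness_1
    - compactness_2
    - max_3d_diameter
  INT:
    - mean
    - median
    - minimum
    - maximum
    - range
    - variance
    - standard_deviation
    - skewness
    - kurtosis
    - energy
    - root_mean_square
    - mean_absolute_deviation
    - robust_mean_absolute_deviation
    - interquartile_range
    - percentile_10
    - percentile_90
    - coefficient_of_variation
    - quartile_coefficient_of_dispersion
  HIST:
    - mean
    - variance
    - skewness
    - kurtosis
    - median
    - minimum
    - maximum
    - mode
    - interquartile_range
    - range
    - percentile_10
    - percentile_90
    - mean_absolute_deviation
    - robust_mean_absolute_deviation
    - coefficient_of_variation
    - quartile_coefficient_of_dispersion
    - entropy
    - uniformity
    - max_gradient
    - max_gradient_level
  GLCM:
    - angular_second_moment
    - contrast
    - correlation
    - variance
    - inverse_difference_moment
    - sum_average
    - sum_entropy
    - entropy
    - difference_entropy
    - dissimilarity
    - inverse_difference
  GLRLM:
    - short_run_emphasis
    - long_run_emphasis
    - gray_level_nonuniformity
    - run_nonuniformity
    - run_percentage
    - low_gray_level_emphasis
    - high_gray_level_emphasis
    - short_run_low_gray_level_emphasis
    - short_run_high_gray_level_emphasis
    - long_run_low_gray_level_emphasis
    - long_run_high_gray_level_emphasis
    - gray_level_variance
    - run_variance
  GLSZM:
    - small_zone_emphasis
    - large_zone_emphasis
    - gray_level_nonuniformity
    - zone_size_nonuniformity
    - zone_percentage
    - low_gray_level_emphasis
    - high_gray_level_emphasis
    - small_zone_low_gray_level_emphasis
    - small_zone_high_gray_level_emphasis
    - large_zone_low_gray_level_emphasis
    - large_zone_high_gray_level_emphasis
    - gray_level_variance
    - zone_size_variance
  NGLDM:
    - low_dependence_emphasis
    - high_dependence_emphasis
    - gray_level_nonuniformity
    - gray_level_nonuniformity_normalized
    - dependence_count_nonuniformity
    - dependence_count_nonuniformity_normalized
    - low_gray_level_count_emphasis
    - high_gray_level_count_emphasis
    - low_dependence_low_gray_level_emphasis
    - low_dependence_high_gray_level_emphasis
    - high_dependence_low_gray_level_emphasis
    - high_dependence_high_gray_level_emphasis
    - gray_level_variance
    - dependence_count_variance
    - dependence_count_entropy
    - dependence_count_energy
  NGTDM:
    - coarseness
    - contrast
    - busyness
    - complexity
    - strength
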