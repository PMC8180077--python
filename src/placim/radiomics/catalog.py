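"""The fixed, ordered 100-feature radiomic catalog.

18 first-order intensity features, 9 two-dimensional shape features and 73
texture features (GLCM 22, GLRLM 16, GLSZM 16, NGTDM 5, GLDM 14). The
composition follows the standard radiomics feature classes; the order here
is the contract for every feature vector and CSV the package produces.
"""

from __future__ import annotations

FIRSTORDER_NAMES = [
    "firstorder_energy",
    "firstorder_total_energy",
    "firstorder_entropy",
    "firstorder_minimum",
    "firstorder_percentile10",
    "firstorder_percentile90",
    "firstorder_maximum",
    "firstorder_mean",
    "firstorder_median",
    "firstorder_interquartile_range",
    "firstorder_range",
    "firstorder_mean_absolute_deviation",
    "firstorder_robust_mean_absolute_deviation",
    "firstorder_root_mean_squared",
    "firstorder_skewness",
    "firstorder_kurtosis",
    "firstorder_variance",
    "firstorder_uniformity",
]

SHAPE_NAMES = [
    "shape_pixel_surface",
    "shape_perimeter",
    "shape_perimeter_surface_ratio",
    "shape_sphericity",
    "shape_maximum_diameter",
    "shape_major_axis_length",
    "shape_minor_axis_length",
    "shape_elongation",
    "shape_spherical_disproportion",
]

GLCM_NAMES = [
    "glcm_autocorrelation",
    "glcm_joint_average",
    "glcm_cluster_prominence",
    "glcm_cluster_shade",
    "glcm_cluster_tendency",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_difference_average",
    "glcm_difference_entropy",
    "glcm_difference_variance",
    "glcm_joint_energy",
    "glcm_joint_entropy",
    "glcm_imc1",
    "glcm_imc2",
    "glcm_idm",
    "glcm_idmn",
    "glcm_id",
    "glcm_idn",
    "glcm_inverse_variance",
    "glcm_maximum_probability",
    "glcm_sum_entropy",
    "glcm_sum_squares",
]

GLRLM_NAMES = [
    "glrlm_short_run_emphasis",
    "glrlm_long_run_emphasis",
    "glrlm_gray_level_nonuniformity",
    "glrlm_gray_level_nonuniformity_normalized",
    "glrlm_run_length_nonuniformity",
    "glrlm_run_length_nonuniformity_normalized",
    "glrlm_run_percentage",
    "glrlm_gray_level_variance",
    "glrlm_run_variance",
    "glrlm_run_entropy",
    "glrlm_low_gray_level_run_emphasis",
    "glrlm_high_gray_level_run_emphasis",
    "glrlm_short_run_low_gray_level_emphasis",
    "glrlm_short_run_high_gray_level_emphasis",
    "glrlm_long_run_low_gray_level_emphasis",
    "glrlm_long_run_high_gray_level_emphasis",
]

GLSZM_NAMES = [
    "glszm_small_area_emphasis",
    "glszm_large_area_emphasis",
    "glszm_gray_level_nonuniformity",
    "glszm_gray_level_nonuniformity_normalized",
    "glszm_size_zone_nonuniformity",
    "glszm_size_zone_nonuniformity_normalized",
    "glszm_zone_percentage",
    "glszm_gray_level_variance",
    "glszm_zone_variance",
    "glszm_zone_entropy",
    "glszm_low_gray_level_zone_emphasis",
    "glszm_high_gray_level_zone_emphasis",
    "glszm_small_area_low_gray_level_emphasis",
    "glszm_small_area_high_gray_level_emphasis",
    "glszm_large_area_low_gray_level_emphasis",
    "glszm_large_area_high_gray_level_emphasis",
]

NGTDM_NAMES = [
    "ngtdm_coarseness",
    "ngtdm_contrast",
    "ngtdm_busyness",
    "ngtdm_complexity",
    "ngtdm_strength",
]

GLDM_NAMES = [
    "gldm_small_dependence_emphasis",
    "gldm_large_dependence_emphasis",
    "gldm_gray_level_nonuniformity",
    "gldm_dependence_nonuniformity",
    "gldm_dependence_nonuniformity_normalized",
    "gldm_gray_level_variance",
    "gldm_dependence_variance",
    "gldm_dependence_entropy",
    "gldm_low_gray_level_emphasis",
    "gldm_high_gray_level_emphasis",
    "gldm_small_dependence_low_gray_level_emphasis",
    "gldm_small_dependence_high_gray_level_emphasis",
    "gldm_large_dependence_low_gray_level_emphasis",
    "gldm_large_dependence_high_gray_level_emphasis",
]

TEXTURE_NAMES = GLCM_NAMES + GLRLM_NAMES + GLSZM_NAMES + NGTDM_NAMES + GLDM_NAMES
ALL_NAMES = FIRSTORDER_NAMES + SHAPE_NAMES + TEXTURE_NAMES

FAMILY_COUNTS = {
    "firstorder": len(FIRSTORDER_NAMES),
    "shape": len(SHAPE_NAMES),
    "texture": len(TEXTURE_NAMES),
}

assert FAMILY_COUNTS == {"firstorder": 18, "shape": 9, "texture": 73}
assert len(ALL_NAMES) == 100 and len(set(ALL_NAMES)) == 100


def family_of(name: str) -> str:
    """Coarse family tag (firstorder / shape / texture) of a feature name."""
    prefix = name.split("_", 1)[0]
    if prefix == "firstorder":
        return "firstorder"
    if prefix == "shape":
        return "shape"
    return "texture"
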