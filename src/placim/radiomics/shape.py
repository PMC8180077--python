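"""2D shape descriptors of a single-component binary mask.

Area is the pixel count; the perimeter uses the weighted boundary-segment
estimator with diagonal correction (as in ``skimage.measure.perimeter``),
which is what makes the circularity of a digitised circle land close
to 1. Axis lengths come from the second central moments of the region
(lengths of the ellipse with the same normalised moments); elongation is
minor/major, so a disk scores ~1 and a line segment ~0.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.measure import regionprops


def shape_features(roi_mask: np.ndarray) -> dict[str, float]:
    m = (np.asarray(roi_mask) > 0).astype(np.uint8)
    if not m.any():
        raise ValueError("empty mask")
    _, n_comp = ndimage.label(m, structure=np.ones((3, 3), dtype=int))
    if n_comp != 1:
        raise ValueError(f"shape features require a single component, found {n_comp}")
    props = regionprops(m)[0]
    area = float(props.area)
    perimeter = float(props.perimeter)
    if perimeter == 0.0:          # single-pixel region: treat as unit square
        perimeter = 4.0
    sphericity = 2.0 * np.sqrt(np.pi * area) / perimeter
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    return {
        "shape_pixel_surface": area,
        "shape_perimeter": perimeter,
        "shape_perimeter_surface_ratio": perimeter / area,
        "shape_sphericity": sphericity,
        "shape_maximum_diameter": float(props.feret_diameter_max),
        "shape_major_axis_length": major,
        "shape_minor_axis_length": minor,
        "shape_elongation": minor / major if major > 0 else 1.0,
        "shape_spherical_disproportion": 1.0 / sphericity,
    }
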