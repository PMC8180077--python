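"""Radiomic feature extraction: the ordered 100-feature vector.

``extract_all`` concatenates 18 first-order intensity features, 9 shape
features of the ROI mask and 73 texture features of the discretized ROI,
in the fixed order of :mod:`placim.radiomics.catalog`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .catalog import (
    ALL_NAMES,
    FAMILY_COUNTS,
    FIRSTORDER_NAMES,
    SHAPE_NAMES,
    TEXTURE_NAMES,
    family_of,
)
from .discretize import DiscretizedRoi, discretize, discretize_values
from .firstorder import first_order_features
from .shape import shape_features
from .texture import (
    glcm_features,
    glcm_matrix,
    gldm_features,
    gldm_matrix,
    glrlm_features,
    glrlm_matrix,
    glszm_features,
    glszm_matrix,
    ngtdm_features,
    texture_features,
)

__all__ = [
    "ALL_NAMES", "FAMILY_COUNTS", "FIRSTORDER_NAMES", "SHAPE_NAMES",
    "TEXTURE_NAMES", "family_of", "DiscretizedRoi", "discretize",
    "discretize_values", "first_order_features", "shape_features",
    "glcm_matrix", "glcm_features", "glrlm_matrix", "glrlm_features",
    "glszm_matrix", "glszm_features", "ngtdm_features", "gldm_matrix",
    "gldm_features", "texture_features", "extract_all", "features_table",
]


def extract_all(image: np.ndarray, roi_mask: np.ndarray,
                n_bins: int = 32) -> np.ndarray:
    """The full 100-element radiomic vector of an image restricted to an ROI.

    Raises with the offending feature family's name if any sub-extractor
    fails; all returned values are finite.
    """
    image = np.asarray(image, dtype=np.float64)
    m = np.asarray(roi_mask) > 0
    if image.shape != m.shape:
        raise ValueError("image and ROI shapes differ")
    if not m.any():
        raise ValueError("empty ROI")
    values: dict[str, float] = {}
    for name, fn in (
        ("firstorder", lambda: first_order_features(image[m], n_bins=n_bins)),
        ("shape", lambda: shape_features(m)),
        ("texture", lambda: texture_features(discretize(image, m, n_bins=n_bins))),
    ):
        try:
            values.update(fn())
        except Exception as exc:  # annotate with the family that failed
            raise type(exc)(f"{name} features: {exc}") from exc
    vec = np.array([values[k] for k in ALL_NAMES], dtype=np.float64)
    if not np.isfinite(vec).all():
        bad = [ALL_NAMES[i] for i in np.flatnonzero(~np.isfinite(vec))]
        raise FloatingPointError(f"non-finite features: {bad}")
    return vec


def features_table(records, roi_masks, n_bins: int = 32) -> pd.DataFrame:
    """Feature matrix for a list of records and matching ROI masks."""
    rows = {}
    for rec, roi in zip(records, roi_masks):
        rows[rec.id] = extract_all(rec.image, roi, n_bins=n_bins)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=ALL_NAMES)
    df.index.name = "id"
    return df
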