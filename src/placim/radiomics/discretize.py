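"""Gray-level discretization of ROI intensities.

Equal-width bins over the ROI's own [min, max]: bin k covers
[min + k*w, min + (k+1)*w) with the last bin closed above, so the maximum
maps to level ``n_bins``. Levels are 1-based; a constant ROI maps to
level 1 everywhere. Because bins are defined from the ROI's own range,
discretization is invariant to affine intensity rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def discretize_values(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Map intensities to integer levels 1..n_bins."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty ROI")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.ones(x.shape, dtype=np.int64)
    levels = np.floor((x - lo) / (hi - lo) * n_bins).astype(np.int64) + 1
    return np.clip(levels, 1, n_bins)


@dataclass
class DiscretizedRoi:
    """Discretized ROI on its bounding-box crop.

    ``levels`` is 0 outside the ROI and 1..n_levels inside, where
    ``n_levels`` is the highest observed level.
    """

    levels: np.ndarray
    n_levels: int

    @property
    def n_pixels(self) -> int:
        return int((self.levels > 0).sum())

    def gray_counts(self) -> np.ndarray:
        """Pixel count per level, index 0 <-> level 1."""
        return np.bincount(self.levels[self.levels > 0],
                           minlength=self.n_levels + 1)[1:]


def discretize(image: np.ndarray, roi_mask: np.ndarray, n_bins: int = 32) -> DiscretizedRoi:
    """Discretize an image restricted to an ROI mask, cropped to its bbox."""
    img = np.asarray(image, dtype=np.float64)
    m = np.asarray(roi_mask) > 0
    if img.shape != m.shape:
        raise ValueError("image and ROI shapes differ")
    if not m.any():
        raise ValueError("empty ROI")
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    img = img[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    m = m[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    levels = np.zeros(img.shape, dtype=np.int64)
    levels[m] = discretize_values(img[m], n_bins)
    return DiscretizedRoi(levels=levels, n_levels=int(levels.max()))
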