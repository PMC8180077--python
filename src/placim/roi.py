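"""ROI construction: outward boundary extension and bounding-rectangle crop.

The analysis region is the segmented placenta extended outward by ``d``
pixels — the extension captures the placenta–myometrium interface where
invasion manifests. Extension is a Euclidean distance-transform threshold
(equivalently, dilation by a Euclidean disk of radius d), clipped at the
image border. Coordinates are 0-based row-major; bounding boxes are
half-open ``(row_min, col_min, row_max, col_max)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

#: extension used when none is given; the best-performing setting upstream
DEFAULT_EXTENSION_PX = 40


@dataclass
class RoiMask:
    mask: np.ndarray            # binary, includes the original placenta
    extension_px: int
    bbox: tuple[int, int, int, int]

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def mask_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Minimal half-open bounding box of the foreground."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("empty mask has no bounding box")
    return int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1


def extend_region(placenta_mask: np.ndarray, d: int) -> RoiMask:
    """Extend the placenta mask outward by d pixels (Euclidean metric)."""
    if d < 0:
        raise ValueError(f"extension must be non-negative, got {d}")
    m = np.asarray(placenta_mask) > 0
    if not m.any():
        raise ValueError("cannot extend an empty mask")
    if d == 0:
        ext = m
    else:
        dist = ndimage.distance_transform_edt(~m)
        ext = dist <= d
    ext = ext.astype(np.uint8)
    return RoiMask(mask=ext, extension_px=int(d), bbox=mask_bbox(ext))


def bounding_rect_crop(image: np.ndarray, roi: RoiMask, pad_to_multiple: int = 1):
    """Crop image and ROI to the ROI's bbox, zero-padded to a size multiple.

    Padding is symmetric (extra pixel goes to the bottom/right) and applies
    per axis up to the next multiple of ``pad_to_multiple``. Returns
    ``(cropped_image, cropped_roi_mask)`` of identical shape.
    """
    if pad_to_multiple < 1:
        raise ValueError("pad_to_multiple must be >= 1")
    if not roi.mask.any():
        raise ValueError("empty ROI cannot be cropped")
    r0, c0, r1, c1 = roi.bbox
    img = np.asarray(image)[r0:r1, c0:c1]
    msk = roi.mask[r0:r1, c0:c1]
    out = []
    for arr in (img, msk):
        h, w = arr.shape
        th = -(-h // pad_to_multiple) * pad_to_multiple
        tw = -(-w // pad_to_multiple) * pad_to_multiple
        pt, pl = (th - h) // 2, (tw - w) // 2
        out.append(np.pad(arr, ((pt, th - h - pt), (pl, tw - w - pl))))
    return out[0], out[1]


def resize_bilinear(image: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of a 2D array to (size, size)."""
    h, w = image.shape
    return ndimage.zoom(np.asarray(image, dtype=np.float64),
                        (size / h, size / w), order=1, grid_mode=True,
                        mode="grid-constant")
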