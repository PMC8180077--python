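"""Reading and writing images, masks and dataset manifests.

Images live in memory as float arrays in [0, 1]; on disk they are 16-bit
grayscale PNG (preferred, avoids quantisation artefacts in texture
features) or single-slice NIfTI. Masks are 8-bit {0, 1} PNG or NIfTI.
Manifests are plain CSV with columns id, image_path, mask_path, label,
plane; paths are stored relative to the manifest's directory.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

MANIFEST_COLUMNS = ["id", "image_path", "mask_path", "label", "plane"]


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a float [0,1] image as 16-bit PNG or NIfTI by extension."""
    path = Path(path)
    img = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    if path.name.endswith((".nii", ".nii.gz")):
        nib.save(nib.Nifti1Image(img.astype(np.float32), affine=np.eye(4)), str(path))
    else:
        iio.imwrite(path, np.round(img * 65535).astype(np.uint16))


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        return np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)
    arr = np.asarray(iio.imread(path), dtype=np.float64)
    info = np.iinfo(np.uint16) if arr.max() > 255 else np.iinfo(np.uint8)
    return arr / info.max


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    path = Path(path)
    m = (np.asarray(mask) > 0).astype(np.uint8)
    if path.name.endswith((".nii", ".nii.gz")):
        nib.save(nib.Nifti1Image(m, affine=np.eye(4)), str(path))
    else:
        iio.imwrite(path, m * 255)


def read_mask(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        arr = np.asarray(nib.load(str(path)).get_fdata())
    else:
        arr = np.asarray(iio.imread(path))
    return (arr > arr.max() / 2 if arr.max() > 0 else arr > 0).astype(np.uint8)


def write_manifest(path: str | Path, rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns {sorted(missing)}")
    return df


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
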