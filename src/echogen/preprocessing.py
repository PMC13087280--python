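"""Geometry alignment and normalization between B-mode images and RF frames.

The clinical acquisition geometry this mirrors: RF frames of 2080 samples x
510 lines, B-mode rasters of 373 x 541 pixels resized to the RF grid, both
padded/cropped to 2048 x 512 so every dimension is a power of two, then
min-max normalized to [0, 1] with global constants fitted on the training
split only.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize as _sk_resize

from .types import BModeImage, NormalizationParams

__all__ = [
    "align_bmode",
    "pad_crop_pow2",
    "fit_normalization",
    "minmax_normalize",
    "denormalize",
]

PAD_COLS = 2        # first and last column repeated in place
CROP_ROWS = 32      # trailing rows dropped


def align_bmode(bmode: BModeImage, target_shape: tuple[int, int],
                flip_axis: int | None = 0) -> BModeImage:
    """Resize a B-mode image to the RF grid and undo the scanner's display
    flip.

    Linear-interpolation resize to ``target_shape`` followed by a flip along
    ``flip_axis`` (default: the axial/row direction; pass ``None`` to skip).
    """
    rows, cols = target_shape
    if rows < 1 or cols < 1:
        raise ValueError("target shape must be positive")
    img = _sk_resize(bmode.pixels, (rows, cols), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    if flip_axis is not None:
        img = np.flip(img, axis=flip_axis)
    return BModeImage(np.clip(img, 0.0, 1.0), bmode.dynamic_range_db,
                      bmode.extent_mm)


def pad_crop_pow2(array: np.ndarray, expected_shape: tuple[int, int] | None = (2080, 510)) -> np.ndarray:
    """Duplicate the first and last column in place (cols + 2) and drop the
    trailing 32 rows (rows - 32), turning 2080 x 510 into 2048 x 512.

    ``expected_shape`` guards against accidental misuse; pass ``None`` to
    apply the same cols+2 / rows-32 contract to other geometries.
    """
    arr = np.asarray(array)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D array")
    if expected_shape is not None and arr.shape != tuple(expected_shape):
        raise ValueError(f"expected shape {expected_shape}, got {arr.shape}")
    if arr.shape[0] <= CROP_ROWS:
        raise ValueError("too few rows to crop")
    out = np.concatenate([arr[:, :1], arr, arr[:, -1:]], axis=1)
    return out[:-CROP_ROWS]


def fit_normalization(arrays, source: str = "train",
                      kind: str = "rf") -> NormalizationParams:
    """Fit global min-max constants over a collection of training arrays."""
    lo = min(float(np.min(a)) for a in arrays)
    hi = max(float(np.max(a)) for a in arrays)
    if kind == "rf":
        return NormalizationParams(rf_min=lo, rf_max=hi, source=source)
    return NormalizationParams(rf_min=0.0, rf_max=1.0,
                               bmode_min=lo, bmode_max=hi, source=source)


def minmax_normalize(array: np.ndarray, params: NormalizationParams,
                     kind: str = "rf") -> np.ndarray:
    """Map to [0, 1] with the training-set constants; out-of-range values
    (possible on the test split) are clipped."""
    lo, hi = ((params.rf_min, params.rf_max) if kind == "rf"
              else (params.bmode_min, params.bmode_max))
    return np.clip((np.asarray(array, dtype=np.float64) - lo) / (hi - lo),
                   0.0, 1.0)


def denormalize(array: np.ndarray, params: NormalizationParams,
                kind: str = "rf") -> np.ndarray:
    lo, hi = ((params.rf_min, params.rf_max) if kind == "rf"
              else (params.bmode_min, params.bmode_max))
    return np.asarray(array, dtype=np.float64) * (hi - lo) + lo
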