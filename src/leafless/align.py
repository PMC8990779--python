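"""Grayscale conversion, similarity (Helmert) registration and patch tiling.

The two acquisition passes of a vineyard row — before and after
defoliation — are taken at different times and positions, so image pairs
differ by an approximate planar similarity.  A 4-parameter Helmert
transform (isotropic scale, rotation, two translations) estimated from
manually clicked keypoint pairs registers the non-occluded pass onto the
occluded one.  Patches are then carved out with a fixed sliding window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import masks

#: ITU-R BT.601 luminance weights
BT601 = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class HelmertParams:
    """Planar similarity: ``target = scale * R(rotation) @ source + translation``.

    Coordinates are 0-based ``(row, col)``; ``rotation`` is in radians.
    """

    scale: float
    rotation: float
    translation: tuple[float, float]

    def __post_init__(self):
        if not self.scale > 0:
            raise ValueError("scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def transform_points(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + np.asarray(self.translation)

    def inverse(self) -> "HelmertParams":
        inv_t = -np.linalg.solve(self.matrix, np.asarray(self.translation))
        return HelmertParams(scale=1.0 / self.scale, rotation=-self.rotation,
                             translation=(float(inv_t[0]), float(inv_t[1])))


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry for patch extraction."""

    window: int = 656
    stride: int = 162

    def __post_init__(self):
        if self.window <= 0 or self.stride <= 0:
            raise ValueError("window and stride must be positive")


def to_grayscale(rgb, weights=BT601) -> np.ndarray:
    """Collapse an 8-bit RGB image to grayscale by luminance weighting."""
    arr = np.asarray(rgb)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {arr.shape}")
    gray = arr.astype(np.float64) @ np.asarray(weights, dtype=np.float64)
    return np.clip(np.round(gray), 0, 255).astype(np.uint8)


def estimate_helmert(src_points, dst_points=None) -> HelmertParams:
    """Least-squares 4-parameter similarity from keypoint correspondences.

    Accepts either two (n, 2) arrays or a single (n, 4) array of
    ``(src_row, src_col, dst_row, dst_col)`` rows.  With the
    parametrisation a = s cos(theta), b = s sin(theta) the model is
    linear, so the fit is closed-form and exact whenever the
    correspondences are consistent with one similarity.
    """
    if dst_points is None:
        pairs = np.asarray(src_points, dtype=float)
        if pairs.ndim != 2 or pairs.shape[1] != 4:
            raise ValueError("expected (n, 4) keypoint rows")
        src, dst = pairs[:, :2], pairs[:, 2:]
    else:
        src = np.asarray(src_points, dtype=float)
        dst = np.asarray(dst_points, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("source and target keypoints must both be (n, 2)")
    if len(src) < 2:
        raise ValueError("need at least two keypoint pairs")
    if np.allclose(src, src[0]):
        raise ValueError("source keypoints are coincident")
    n = len(src)
    # rows: [r, -c, 1, 0] @ [a b tr tc]^T = r';  [c, r, 0, 1] -> c'
    A = np.zeros((2 * n, 4))
    A[0::2, 0], A[0::2, 1], A[0::2, 2] = src[:, 0], -src[:, 1], 1.0
    A[1::2, 0], A[1::2, 1], A[1::2, 3] = src[:, 1], src[:, 0], 1.0
    y = dst.reshape(-1)
    (a, b, tr, tc), *_ = np.linalg.lstsq(A, y, rcond=None)
    return HelmertParams(scale=float(np.hypot(a, b)),
                         rotation=float(np.arctan2(b, a)),
                         translation=(float(tr), float(tc)))


def apply_helmert(image, params: HelmertParams, out_shape=None,
                  is_mask: bool | None = None) -> np.ndarray:
    """Resample an image or mask through a similarity transform.

    The output grid has shape ``out_shape`` (default: input shape);
    pixels mapping outside the source are filled with black.  Masks are
    resampled nearest-neighbour so the label alphabet survives; the
    decision is automatic (all values in {0,127,255}) unless ``is_mask``
    is given.
    """
    arr = masks.as_gray(image)
    if is_mask is None:
        is_mask = bool(np.isin(arr, masks.CLASS_VALUES).all())
    out_shape = arr.shape if out_shape is None else tuple(out_shape)
    inv = params.inverse()
    out = ndimage.affine_transform(
        arr.astype(np.float32), matrix=inv.matrix, offset=np.asarray(inv.translation),
        output_shape=out_shape, order=0 if is_mask else 1, mode="constant", cval=0.0)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def extract_patches(image, config: WindowConfig | None = None):
    """All fully-inside sliding-window crops with their (row, col) offsets.

    Offsets are multiples of the stride; the count per axis is
    ``floor((dim - window) / stride) + 1``.  Windows are half-open
    ``[off, off + window)``.
    """
    config = config or WindowConfig()
    arr = np.asarray(image)
    h, w = arr.shape[:2]
    if h < config.window or w < config.window:
        raise ValueError(
            f"image {arr.shape[:2]} smaller than window {config.window}")
    out = []
    for i in range((h - config.window) // config.stride + 1):
        for j in range((w - config.window) // config.stride + 1):
            r, c = i * config.stride, j * config.stride
            out.append(((r, c), arr[r: r + config.window, c: c + config.window]))
    return out


class HelmertTransform:
    """Estimator-style interface to Helmert registration.

    ``fit(src, dst)`` estimates the similarity; ``transform(points)``
    maps source coordinates and ``transform_image(image)`` resamples an
    image onto the target grid.  Fitted parameters live in ``params_``
    with the usual ``scale_``, ``rotation_``, ``translation_`` aliases.
    """

    def __init__(self):
        pass

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "HelmertTransform":
        if params:
            raise ValueError(f"unknown parameters {sorted(params)}")
        return self

    def fit(self, src_points, dst_points=None) -> "HelmertTransform":
        self.params_ = estimate_helmert(src_points, dst_points)
        self.scale_ = self.params_.scale
        self.rotation_ = self.params_.rotation
        self.translation_ = self.params_.translation
        return self

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("HelmertTransform is not fitted yet")

    def transform(self, points) -> np.ndarray:
        self._check_fitted()
        return self.params_.transform_points(points)

    def transform_image(self, image, out_shape=None, is_mask=None) -> np.ndarray:
        self._check_fitted()
        return apply_helmert(image, self.params_, out_shape=out_shape,
                             is_mask=is_mask)


def read_keypoints_csv(path) -> np.ndarray:
    """Read ``src_row,src_col,dst_row,dst_col`` keypoint rows."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = ["src_row", "src_col", "dst_row", "dst_col"]
    if not set(cols) <= set(df.columns):
        raise ValueError(f"keypoint CSV must have columns {cols}")
    return df[cols].to_numpy(dtype=float)
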