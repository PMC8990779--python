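"""Berry masks and pixel-level comparison metrics.

A *berry mask* is a three-class per-pixel labelling that makes touching
berries countable: the interior of every berry carries the label 255
(``BERRY``), a thin separating ring carries 127 (``BERRY_EDGE``) and
everything else is 0 (``BACKGROUND``).  Masks travel through the package
as plain ``uint8`` numpy arrays; the functions here validate, clean up
and compare them.

Generated masks coming out of the translation network are continuous
images in [0, 255]; :func:`postprocess_mask` snaps every pixel back onto
the three legal values before any counting is done.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

BACKGROUND = 0
BERRY_EDGE = 127
BERRY = 255

#: the full label alphabet, in increasing order
CLASS_VALUES = (BACKGROUND, BERRY_EDGE, BERRY)

CLASS_NAMES = {BACKGROUND: "background", BERRY_EDGE: "berry-edge", BERRY: "berry"}

# thresholding bands for raw generated masks: [0, 50) -> 0, [50, 180) -> 127,
# [180, 255] -> 255.  Boundary pixels go to the higher class so the binning is
# total and deterministic.
_THRESHOLDS = (50, 180)

# generation-map categories (reference class -> generated class)
NC = 0          # no change
B_BE = 1        # berry <-> berry-edge, acceptable
BG_TO_B = 2     # berry generated on background reference
BG_TO_BE = 3    # edge generated on background reference
B_TO_BG = 4     # berry reference lost to background
BE_TO_BG = 5    # edge reference lost to background

GENERATION_CATEGORIES = (NC, B_BE, BG_TO_B, BG_TO_BE, B_TO_BG, BE_TO_BG)

GENERATION_CATEGORY_NAMES = {
    NC: "no-change",
    B_BE: "berry<->edge",
    BG_TO_B: "background->berry",
    BG_TO_BE: "background->edge",
    B_TO_BG: "berry->background",
    BE_TO_BG: "edge->background",
}

#: default legend; orange hues flag spurious generation, blue hues flag loss
DEFAULT_LEGEND = {
    NC: (255, 255, 255),
    B_BE: (255, 178, 102),
    BG_TO_B: (204, 85, 0),
    BG_TO_BE: (255, 140, 26),
    B_TO_BG: (0, 51, 153),
    BE_TO_BG: (51, 119, 255),
}

#: categories that are acceptable for downstream counting (berry/edge swaps do
#: not move berries in or out of the scene)
ACCEPTABLE_CATEGORIES = frozenset({NC, B_BE})


def as_gray(image) -> np.ndarray:
    """Validate a 2-D grayscale image with intensities in [0, 255]."""
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a non-empty 2-D image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if np.any((arr < 0) | (arr > 255)):
            raise ValueError("intensities must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def as_mask(mask) -> np.ndarray:
    """Validate a three-class berry mask (labels exactly {0, 127, 255})."""
    arr = as_gray(mask)
    if not np.isin(arr, CLASS_VALUES).all():
        bad = np.setdiff1d(np.unique(arr), CLASS_VALUES)
        raise ValueError(f"mask contains non-class values {bad.tolist()}")
    return arr


def postprocess_mask(raw) -> np.ndarray:
    """Snap a raw generated mask onto the class values {0, 127, 255}.

    Pixels in [0, 50) become background, [50, 180) berry-edge and
    [180, 255] berry.  The mapping is pixel-wise and idempotent.
    """
    arr = as_gray(raw)
    lut = np.empty(256, dtype=np.uint8)
    lut[: _THRESHOLDS[0]] = BACKGROUND
    lut[_THRESHOLDS[0]: _THRESHOLDS[1]] = BERRY_EDGE
    lut[_THRESHOLDS[1]:] = BERRY
    return lut[arr]


def class_area(mask, cls: int) -> int:
    """Number of pixels of class ``cls`` in ``mask`` (the area F_c)."""
    if cls not in CLASS_VALUES:
        raise ValueError(f"unknown class label {cls!r}; expected one of {CLASS_VALUES}")
    return int(np.count_nonzero(as_mask(mask) == cls))


def area_table(mask) -> dict[int, int]:
    """Per-class pixel counts; values sum to the mask size."""
    m = as_mask(mask)
    return {cls: int(np.count_nonzero(m == cls)) for cls in CLASS_VALUES}


def iou(a, b, cls: int) -> float:
    """Intersection over union of one class between two masks.

    An empty union (the class absent from both masks) counts as perfect
    agreement and returns 1.0, which keeps per-patch aggregation free of
    NaNs.
    """
    if cls not in CLASS_VALUES:
        raise ValueError(f"unknown class label {cls!r}")
    ma, mb = as_mask(a), as_mask(b)
    if ma.shape != mb.shape:
        raise ValueError(f"shape mismatch: {ma.shape} vs {mb.shape}")
    sa, sb = ma == cls, mb == cls
    union = np.count_nonzero(sa | sb)
    if union == 0:
        return 1.0
    return float(np.count_nonzero(sa & sb) / union)


def pearson_correlation(a, b, mode: str = "labels") -> float:
    """Pearson product-moment correlation between two images or masks.

    With ``mode="labels"`` (the default) the raw pixel values are
    correlated after row-major flattening.  ``mode="onehot"`` instead
    stacks one indicator plane per class and correlates the stacked
    binary vectors, which weights the three classes equally.
    """
    xa, xb = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    if xa.shape != xb.shape:
        raise ValueError(f"shape mismatch: {xa.shape} vs {xb.shape}")
    if mode == "labels":
        va, vb = xa.ravel(), xb.ravel()
    elif mode == "onehot":
        va = np.concatenate([(xa == c).ravel() for c in CLASS_VALUES]).astype(float)
        vb = np.concatenate([(xb == c).ravel() for c in CLASS_VALUES]).astype(float)
    else:
        raise ValueError(f"unknown correlation mode {mode!r}")
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(np.corrcoef(va, vb)[0, 1])


def merge_to_binary(mask) -> np.ndarray:
    """Merge berry and berry-edge into a single berry class (labels {0, 255})."""
    m = as_mask(mask)
    out = m.copy()
    out[m == BERRY_EDGE] = BERRY
    return out


def generation_map(reference, generated, binary: bool = False) -> np.ndarray:
    """Categorical per-pixel difference image between two masks.

    Pixels where the classes agree are ``NC``; berry/edge swaps are the
    acceptable ``B_BE`` category; any transition that moves mass between
    background and a berry class is flagged with its own category.  With
    ``binary=True`` both masks are first merged to two classes, which
    leaves only the non-acceptable categories visible.
    """
    ref, gen = as_mask(reference), as_mask(generated)
    if ref.shape != gen.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {gen.shape}")
    if binary:
        ref, gen = merge_to_binary(ref), merge_to_binary(gen)
    out = np.full(ref.shape, NC, dtype=np.uint8)
    diff = ref != gen
    ref_bg, gen_bg = ref == BACKGROUND, gen == BACKGROUND
    out[diff & ~ref_bg & ~gen_bg] = B_BE
    out[diff & ref_bg & (gen == BERRY)] = BG_TO_B
    out[diff & ref_bg & (gen == BERRY_EDGE)] = BG_TO_BE
    out[diff & (ref == BERRY) & gen_bg] = B_TO_BG
    out[diff & (ref == BERRY_EDGE) & gen_bg] = BE_TO_BG
    return out


def render_generation_map(categories, legend=None) -> np.ndarray:
    """Render a generation map to an RGB image using ``legend`` colours."""
    legend = dict(DEFAULT_LEGEND if legend is None else legend)
    cats = np.asarray(categories)
    rgb = np.zeros(cats.shape + (3,), dtype=np.uint8)
    for cat, color in legend.items():
        rgb[cats == cat] = color
    return rgb


def read_image(path) -> np.ndarray:
    """Read a single-channel 8-bit PNG as a 2-D uint8 array."""
    import imageio.v3 as iio

    arr = iio.imread(Path(path))
    if arr.ndim == 3:  # tolerate grayscale saved with redundant channels
        arr = arr[..., 0]
    return as_gray(arr)


def write_image(path, image) -> None:
    """Write a 2-D uint8 array (grayscale image, mask, or RGB map) as PNG."""
    import imageio.v3 as iio

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def write_generation_map(path, categories, legend=None) -> None:
    """Write a generation map PNG next to a JSON legend file."""
    legend = dict(DEFAULT_LEGEND if legend is None else legend)
    path = Path(path)
    write_image(path, render_generation_map(categories, legend))
    meta = {
        GENERATION_CATEGORY_NAMES[cat]: list(color) for cat, color in legend.items()
    }
    path.with_suffix(".legend.json").write_text(json.dumps(meta, indent=2))
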