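"""Image-comparison procedures for validating renderings.

Two complementary probes, both qualitative aids rather than quantitative
metrics, used to compare screenshots of the same scene rendered by different
engines:

* **difference images** (volume renderings): per-pixel absolute difference,
  converted to greyscale luminance, then smoothed with a 3x3 box mean
  (radius one pixel) to suppress sub-pixel co-registration artefacts;
* **edge overlays** (surface renderings): Sobel gradient-magnitude edges of
  each input, binarised and painted in per-input solid colours over white,
  so geometric agreement shows as coincident outlines while lighting and
  material differences are suppressed.

Inputs are assumed co-registered; an optional integer-pixel shift search is
provided for roughly aligned pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .texture import TextureImage

#: Rec. 601 luma weights used for the black-&-white conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class ComparisonReport:
    """Difference image + summary statistics (values in [0, 1])."""

    difference: np.ndarray  # (h, w) float64 in [0,1]
    mean: float
    max: float


def _as_rgb(t: TextureImage) -> np.ndarray:
    return t.pixels[:, :, :3].astype(np.float64) / 255.0


def _check_dims(a: TextureImage, b: TextureImage) -> None:
    if a.pixels.shape[:2] != b.pixels.shape[:2]:
        raise ValidationError(
            f"image dimensions differ: {a.pixels.shape[:2]} vs {b.pixels.shape[:2]}"
        )


def difference_image(a: TextureImage, b: TextureImage) -> ComparisonReport:
    """Smoothed greyscale difference image of two equally-sized images.

    Per-channel ``|a - b|``, luminance-converted, then 3x3 box mean with
    edge replication; statistics are computed on the smoothed result.
    Symmetric in its arguments.
    """
    _check_dims(a, b)
    diff = np.abs(_as_rgb(a) - _as_rgb(b))
    grey = diff @ _LUMA
    smoothed = ndimage.uniform_filter(grey, size=3, mode="nearest")
    return ComparisonReport(smoothed, float(smoothed.mean()), float(smoothed.max()))


def edge_mask(t: TextureImage, threshold: float = 0.0) -> np.ndarray:
    """Boolean edge mask: Sobel gradient magnitude of the luminance > threshold.

    The default threshold keeps every pixel with any non-zero gradient.
    Invariant under a global intensity offset (the gradient removes it).
    """
    grey = _as_rgb(t) @ _LUMA
    gx = ndimage.sobel(grey, axis=1, mode="nearest")
    gy = ndimage.sobel(grey, axis=0, mode="nearest")
    mag = np.hypot(gx, gy)
    return mag > threshold


def edge_overlay(
    a: TextureImage,
    b: TextureImage,
    colour_a: tuple[float, float, float] = (0.0, 0.3, 1.0),
    colour_b: tuple[float, float, float] = (1.0, 0.5, 0.0),
    threshold: float = 0.0,
) -> TextureImage:
    """Overlay the binary edge masks of two images in solid colours on white.

    Pixels on *a*'s edges are painted ``colour_a``; pixels on *b*'s edges are
    painted ``colour_b`` *over* a's colour where the masks overlap (so
    coincident geometry reads in b's colour).
    """
    _check_dims(a, b)
    h, w = a.pixels.shape[:2]
    out = np.ones((h, w, 3), dtype=np.float64)
    ma = edge_mask(a, threshold)
    mb = edge_mask(b, threshold)
    out[ma] = np.asarray(colour_a, dtype=np.float64)
    out[mb] = np.asarray(colour_b, dtype=np.float64)
    return TextureImage.from_array(out)


def best_integer_shift(
    a: TextureImage, b: TextureImage, max_shift: int = 4
) -> tuple[int, int]:
    """Search integer (dy, dx) shifts of *b* minimising the mean difference.

    A small helper for roughly-aligned screenshot pairs; exhaustive over the
    (2*max_shift+1)^2 window, comparing the overlapping region only.
    """
    _check_dims(a, b)
    ga = _as_rgb(a) @ _LUMA
    gb = _as_rgb(b) @ _LUMA
    h, w = ga.shape
    best = (0, 0)
    best_err = np.inf
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            ya0, yb0 = max(0, dy), max(0, -dy)
            xa0, xb0 = max(0, dx), max(0, -dx)
            hh, ww = h - abs(dy), w - abs(dx)
            if hh <= 0 or ww <= 0:
                continue
            err = float(
                np.abs(
                    ga[ya0 : ya0 + hh, xa0 : xa0 + ww]
                    - gb[yb0 : yb0 + hh, xb0 : xb0 + ww]
                ).mean()
            )
            if err < best_err:
                best_err, best = err, (dy, dx)
    return best
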