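"""Texture compression for embedded 3-d figures.

Two containers are used, chosen by the texture's alpha channel:

* textures that are *entirely opaque* (no pixel with opacity below 1.0 —
  typically surface-mesh textures) are stored as JPEG;
* textures *with transparency* (volume-rendering slices, billboards) are
  stored as palette PNG with at most 256 unique RGBA colours, selected by
  median-cut over RGBA (alpha weighted equally with R, G, B) and applied with
  Floyd-Steinberg error diffusion.

Against a raw 32-bit-per-pixel bitmap this typically halves the stored size
or better; :func:`savings_ratio` reports the achieved fraction.

When a transparent texture already has no more colours than the palette
budget, the palette is exact and the encoding is lossless (dithering is a
no-op by construction and is skipped).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from PIL import Image

from .errors import ParseError, ValidationError

#: Floyd-Steinberg error-diffusion weights for the pixel to the right, and the
#: three pixels below (left, centre, right).  Plain raster order, no serpentine.
_FS_WEIGHTS = (7 / 16, 3 / 16, 5 / 16, 1 / 16)


@dataclass
class TextureImage:
    """RGBA raster texture, 8 bits per channel, channels in [0, 1]."""

    pixels: np.ndarray  # (h, w, 4) uint8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 4:
            raise ValidationError("texture pixels must have shape (h, w, 4)")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("texture must be at least 1x1")
        if px.dtype != np.uint8:
            if np.issubdtype(px.dtype, np.floating):
                if px.min() < 0 or px.max() > 1:
                    raise ValidationError("float texture channels must lie in [0,1]")
                px = np.round(px * 255).astype(np.uint8)
            else:
                px = px.astype(np.uint8)
        self.pixels = px

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "TextureImage":
        """Build from an (h, w, 3|4) array, float in [0,1] or uint8."""
        arr = np.asarray(arr)
        if arr.ndim == 3 and arr.shape[2] == 3:
            alpha = (
                np.ones(arr.shape[:2], dtype=arr.dtype)
                if np.issubdtype(arr.dtype, np.floating)
                else np.full(arr.shape[:2], 255, dtype=arr.dtype)
            )
            arr = np.dstack([arr, alpha])
        return cls(arr)

    def digest(self) -> str:
        import hashlib

        return hashlib.sha256(self.pixels.tobytes()).hexdigest()


def classify_texture(t: TextureImage) -> str:
    """Return ``"opaque"`` iff no pixel has opacity below 1.0, else ``"transparent"``."""
    if t.pixels.size == 0:
        raise ValidationError("cannot classify an empty texture")
    return "opaque" if int(t.pixels[:, :, 3].min()) == 255 else "transparent"


# -- palette quantization -----------------------------------------------------


def _median_cut(colours: np.ndarray, counts: np.ndarray, max_colours: int) -> np.ndarray:
    """Median-cut palette selection over RGBA, alpha weighted like R, G, B.

    *colours* is the (n, 4) array of distinct RGBA values, *counts* their pixel
    frequencies.  Returns a (k, 4) uint8 palette, k <= max_colours, where each
    box contributes its count-weighted mean colour.
    """
    boxes = [np.arange(len(colours))]
    while len(boxes) < max_colours:
        # split the box with the largest count-weighted channel spread
        best, best_spread, best_axis = None, -1.0, 0
        for bi, box in enumerate(boxes):
            if len(box) < 2:
                continue
            spread = colours[box].max(axis=0) - colours[box].min(axis=0)
            axis = int(np.argmax(spread))
            if float(spread[axis]) > best_spread:
                best, best_spread, best_axis = bi, float(spread[axis]), axis
        if best is None or best_spread <= 0:
            break
        box = boxes.pop(best)
        order = box[np.argsort(colours[box, best_axis], kind="stable")]
        cum = np.cumsum(counts[order])
        half = cum[-1] / 2.0
        split = int(np.searchsorted(cum, half)) + 1
        split = min(max(split, 1), len(order) - 1)
        boxes.append(order[:split])
        boxes.append(order[split:])
    palette = []
    for box in boxes:
        w = counts[box].astype(np.float64)
        mean = (colours[box] * w[:, None]).sum(axis=0) / w.sum()
        palette.append(np.round(mean))
    return np.clip(np.array(palette, dtype=np.float64), 0, 255).astype(np.uint8)


def _floyd_steinberg(pixels: np.ndarray, palette: np.ndarray) -> np.ndarray:
    """Map pixels to palette indices with Floyd-Steinberg error diffusion.

    Plain left-to-right, top-to-bottom raster order; the quantization error at
    each pixel is diffused to the yet-unvisited neighbours with weights
    7/16 (right), 3/16 (below-left), 5/16 (below), 1/16 (below-right).
    Distance is euclidean in RGBA with equal channel weights.
    """
    h, w, _ = pixels.shape
    work = pixels.astype(np.float64)
    pal = palette.astype(np.float64)
    out = np.zeros((h, w), dtype=np.uint16)
    wr, wbl, wb, wbr = _FS_WEIGHTS
    for y in range(h):
        for x in range(w):
            old = work[y, x]
            idx = int(np.argmin(((pal - old) ** 2).sum(axis=1)))
            out[y, x] = idx
            err = old - pal[idx]
            if x + 1 < w:
                work[y, x + 1] += err * wr
            if y + 1 < h:
                if x > 0:
                    work[y + 1, x - 1] += err * wbl
                work[y + 1, x] += err * wb
                if x + 1 < w:
                    work[y + 1, x + 1] += err * wbr
    return out


def quantize_rgba(t: TextureImage, max_colours: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Quantize a texture to at most *max_colours* distinct RGBA values.

    Returns ``(palette (k,4) uint8, indices (h,w) uint16)``.  If the input
    already has at most *max_colours* distinct RGBA tuples the palette is the
    exact colour set and the mapping is lossless; otherwise median-cut picks
    the palette and Floyd-Steinberg dithering assigns pixels.
    """
    if not (2 <= max_colours <= 256):
        raise ValidationError("max colours must lie in [2, 256]")
    px = t.pixels
    flat = px.reshape(-1, 4)
    colours, inverse, counts = np.unique(
        flat, axis=0, return_inverse=True, return_counts=True
    )
    if len(colours) <= max_colours:
        return colours.copy(), inverse.reshape(px.shape[:2]).astype(np.uint16)
    palette = _median_cut(colours, counts, max_colours)
    # palette rows may coincide after rounding; keep unique, order-preserving
    _, keep = np.unique(palette, axis=0, return_index=True)
    palette = palette[np.sort(keep)]
    indices = _floyd_steinberg(px, palette)
    return palette, indices


# -- containers ---------------------------------------------------------------


def encode_texture(
    t: TextureImage,
    jpeg_quality: int = 90,
    max_colours: int = 256,
) -> tuple[bytes, str]:
    """Encode a texture with the policy keyed on its transparency.

    Entirely-opaque textures go to JPEG at *jpeg_quality*; textures with any
    transparent pixel go to palette PNG with at most *max_colours* distinct
    RGBA values.  Returns ``(encoded bytes, container tag)`` with tag
    ``"jpeg"`` or ``"png"``.
    """
    if not (1 <= jpeg_quality <= 100):
        raise ValidationError("jpeg quality must lie in [1, 100]")
    kind = classify_texture(t)
    buf = io.BytesIO()
    if kind == "opaque":
        img = Image.fromarray(t.pixels[:, :, :3], mode="RGB")
        img.save(buf, format="JPEG", quality=jpeg_quality)
        return buf.getvalue(), "jpeg"
    palette, indices = quantize_rgba(t, max_colours)
    img = Image.fromarray(indices.astype(np.uint8), mode="P")
    img.putpalette(palette[:, :3].reshape(-1).tobytes(), rawmode="RGB")
    img.save(buf, format="PNG", transparency=bytes(palette[:, 3].tolist()))
    return buf.getvalue(), "png"


def decode_texture(data: bytes) -> TextureImage:
    """Decode JPEG/PNG bytes back to an RGBA texture (test/verification path)."""
    try:
        img = Image.open(io.BytesIO(data))
        img.load()
    except Exception as exc:  # Pillow raises various types
        raise ParseError(f"undecodable texture stream: {exc}") from exc
    return TextureImage(np.asarray(img.convert("RGBA")))


def savings_ratio(t: TextureImage, encoded: bytes) -> float:
    """Size saving vs an uncompressed 32-bit-per-pixel bitmap of *t*.

    ``1 - len(encoded) / (w*h*4)``; negative when encoding inflates the data.
    """
    raw = t.width * t.height * 4
    return 1.0 - len(encoded) / raw
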