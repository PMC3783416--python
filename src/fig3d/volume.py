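"""Slice-based volume rendering pipeline.

A volumetric image enters as a stack of greyscale slices (TIFF/PNG/TGA files,
a NIfTI image, or the XRW interchange container defined below), is normalised
to a 16-bit intensity scale, mapped through a transfer function (colourmap +
opacity ramp) to per-voxel RGBA, and finally cut into *three orthogonal slice
sets*: for each axis, one pre-shaded RGBA texture per voxel plane
perpendicular to that axis.  A PDF viewer shows only the set whose axis best
aligns with the camera, switching sets as the camera crosses the volume's
diagonals.

Because opacity accumulates exponentially along sight-lines
(``A = 1 - (1-a)^n`` for n slices of alpha a under source-over blending), an
anisotropic volume composites to different opacities along different axes,
which makes the set switches visibly jump.  :func:`rescale_opacity` equalizes
this by raising per-texel transparency to a per-axis power,
``a' = 1 - (1-a)^f``, with the axis-length ratios as the default factors; a
:func:`composite_slices` oracle verifies the equalization.

XRW dialect used by this package: magic ``XRW2``, three little-endian uint32
dims (nx, ny, nz), three little-endian float32 spacings, then nx*ny*nz
little-endian uint16 samples, x fastest, then y, then z.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .errors import ParseError, ValidationError
from .texture import TextureImage

XRW_MAGIC = b"XRW2"
INTENSITY_MAX = 65535

AXES = ("x", "y", "z")


@dataclass
class Volume:
    """Normalised 16-bit volumetric image with voxel spacing.

    ``samples`` has shape (nz, ny, nx) (C order, so x is the fastest axis on
    disk) and dtype uint16.
    """

    samples: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        s = np.asarray(self.samples)
        if s.ndim != 3 or min(s.shape) < 1:
            raise ValidationError("volume samples must be a non-empty 3-d array")
        if s.dtype != np.uint16:
            if s.min() < 0 or s.max() > INTENSITY_MAX:
                raise ValidationError("samples must lie in [0, 65535]")
            s = s.astype(np.uint16)
        self.samples = s
        sp = tuple(float(v) for v in self.spacing)
        if len(sp) != 3 or any(v <= 0 for v in sp):
            raise ValidationError("spacing must be three positive lengths")
        self.spacing = sp

    @property
    def dims(self) -> tuple[int, int, int]:
        """(nx, ny, nz)."""
        nz, ny, nx = self.samples.shape
        return nx, ny, nz

    def subsample(self, stride: Sequence[int] | int) -> "Volume":
        """Integer-stride decimation per axis (file-size control)."""
        if isinstance(stride, int):
            stride = (stride, stride, stride)
        sx, sy, sz = (int(v) for v in stride)
        if min(sx, sy, sz) < 1:
            raise ValidationError("subsample strides must be >= 1")
        return Volume(
            self.samples[::sz, ::sy, ::sx].copy(),
            (self.spacing[0] * sx, self.spacing[1] * sy, self.spacing[2] * sz),
        )


# -- XRW container ------------------------------------------------------------


def write_xrw(volume: Volume) -> bytes:
    nx, ny, nz = volume.dims
    head = XRW_MAGIC + struct.pack("<3I3f", nx, ny, nz, *volume.spacing)
    return head + volume.samples.astype("<u2").tobytes()


def read_xrw(data: bytes) -> Volume:
    if len(data) < 28:
        raise ParseError("XRW stream shorter than header")
    if data[:4] != XRW_MAGIC:
        raise ParseError(f"bad XRW magic: {data[:4]!r}")
    nx, ny, nz, dx, dy, dz = struct.unpack_from("<3I3f", data, 4)
    if min(nx, ny, nz) < 1:
        raise ParseError(f"XRW dims must be >= 1, got {nx}x{ny}x{nz}")
    need = 28 + 2 * nx * ny * nz
    if len(data) < need:
        raise ParseError(f"XRW payload truncated: need {need} bytes, have {len(data)}")
    samples = np.frombuffer(data, dtype="<u2", count=nx * ny * nz, offset=28)
    return Volume(samples.reshape(nz, ny, nx).copy(), (dx, dy, dz))


def save_xrw(volume: Volume, path: str | Path) -> None:
    Path(path).write_bytes(write_xrw(volume))


def load_xrw(path: str | Path) -> Volume:
    return read_xrw(Path(path).read_bytes())


# -- slice stacking -----------------------------------------------------------


def stack_to_volume(
    slices: Sequence[np.ndarray],
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
) -> Volume:
    """Stack 2-d greyscale slices into a normalised 16-bit volume.

    Slice k becomes the plane z=k (first array row = y=0).  Intensities are
    rescaled affinely over the whole stack so the global minimum maps to 0 and
    the global maximum to 65535; a constant stack maps to all zeros.
    """
    if len(slices) == 0:
        raise ValidationError("need at least one slice")
    arrs = []
    for i, s in enumerate(slices):
        a = np.asarray(s, dtype=np.float64)
        if a.ndim == 3:  # collapse RGB(A) slices to luminance-free mean grey
            a = a[:, :, : min(3, a.shape[2])].mean(axis=2)
        if a.ndim != 2:
            raise ValidationError(f"slice {i} is not 2-d")
        arrs.append(a)
    shape0 = arrs[0].shape
    for i, a in enumerate(arrs):
        if a.shape != shape0:
            raise ValidationError(
                f"slice {i} has shape {a.shape}, expected {shape0}"
            )
    stack = np.stack(arrs, axis=0)  # (nz, ny, nx)
    if not np.all(np.isfinite(stack)):
        raise ValidationError("slices contain non-finite values")
    lo, hi = float(stack.min()), float(stack.max())
    if hi > lo:
        norm = (stack - lo) / (hi - lo) * INTENSITY_MAX
    else:
        norm = np.zeros_like(stack)
    return Volume(np.round(norm).astype(np.uint16), tuple(spacing))


def load_slice_stack(paths: Sequence[str | Path]) -> list[np.ndarray]:
    """Read greyscale slice images; callers sort paths (alphabetical = ascending z)."""
    import imageio.v3 as iio

    return [np.asarray(iio.imread(p)) for p in paths]


def load_nifti(path: str | Path) -> Volume:
    """Ingest a NIfTI image through the same global min-max normalisation."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValidationError(f"expected a 3-d NIfTI image, got {data.ndim}-d")
    zooms = img.header.get_zooms()[:3]
    # nibabel axis order is (x, y, z); volume storage is (z, y, x)
    return stack_to_volume(
        [data[:, :, k].T for k in range(data.shape[2])],
        (float(zooms[0]), float(zooms[1]), float(zooms[2])),
    )


# -- transfer functions -------------------------------------------------------


def _cmap_greyscale(t: np.ndarray) -> np.ndarray:
    return np.stack([t, t, t], axis=-1)


def _cmap_hotiron(t: np.ndarray) -> np.ndarray:
    """Black -> red -> yellow -> white piecewise-linear ramp (breaks 0, 1/3, 2/3, 1)."""
    r = np.clip(3 * t, 0, 1)
    g = np.clip(3 * t - 1, 0, 1)
    b = np.clip(3 * t - 2, 0, 1)
    return np.stack([r, g, b], axis=-1)


COLOURMAPS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "greyscale": _cmap_greyscale,
    "hotiron": _cmap_hotiron,
}


@dataclass
class TransferFunction:
    """Map from normalised intensity to colour and opacity.

    The colourmap is a named map (``greyscale`` or ``hotiron``) or any
    callable taking normalised intensity in [0,1] to RGB in [0,1].  The
    opacity ramp is linear over the intensity window [lo, hi] (on the
    0..65535 scale): 0 below lo, ``alpha_max`` above hi — hence alpha is
    non-decreasing in intensity.
    """

    colourmap: str | Callable[[np.ndarray], np.ndarray] = "greyscale"
    window: tuple[float, float] = (0.0, float(INTENSITY_MAX))
    alpha_max: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = (float(v) for v in self.window)
        if not (0 <= lo < hi <= INTENSITY_MAX):
            raise ValidationError("opacity window must satisfy 0 <= lo < hi <= 65535")
        self.window = (lo, hi)
        if not (0.0 <= float(self.alpha_max) <= 1.0):
            raise ValidationError("alpha_max must lie in [0,1]")
        if isinstance(self.colourmap, str) and self.colourmap not in COLOURMAPS:
            raise ValidationError(
                f"unknown colourmap {self.colourmap!r}; known: {sorted(COLOURMAPS)}"
            )

    def colours(self, t: np.ndarray) -> np.ndarray:
        fn = COLOURMAPS[self.colourmap] if isinstance(self.colourmap, str) else self.colourmap
        return np.clip(fn(np.asarray(t, dtype=np.float64)), 0.0, 1.0)

    def alphas(self, intensity: np.ndarray) -> np.ndarray:
        lo, hi = self.window
        ramp = (np.asarray(intensity, dtype=np.float64) - lo) / (hi - lo)
        return np.clip(ramp, 0.0, 1.0) * self.alpha_max


def apply_transfer(volume: Volume, tf: TransferFunction) -> np.ndarray:
    """Per-voxel RGBA grid, float64 in [0,1], shape (nz, ny, nx, 4)."""
    intensity = volume.samples.astype(np.float64)
    rgb = tf.colours(intensity / INTENSITY_MAX)
    alpha = tf.alphas(intensity)
    return np.concatenate([rgb, alpha[..., None]], axis=-1)


# -- slice sets ---------------------------------------------------------------


@dataclass
class SliceSet:
    """Ordered stack of pre-shaded RGBA textures perpendicular to one axis.

    Texture k corresponds to the voxel plane at coordinate k along ``axis``
    (ascending).  In-plane texel axes follow the cyclic convention
    x->(y,z), y->(z,x), z->(x,y): texel row index walks the first axis of the
    pair, texel column index the second.
    """

    axis: str
    textures: list[TextureImage] = field(default_factory=list)
    opacity_factor: float = 1.0

    def __len__(self) -> int:
        return len(self.textures)


def _plane(rgba: np.ndarray, axis: str, k: int) -> np.ndarray:
    # rgba is (nz, ny, nx, 4); returned plane is (rows=first cyclic axis,
    # cols=second cyclic axis, 4)
    if axis == "x":  # plane over (y, z)
        return rgba[:, :, k, :].transpose(1, 0, 2)  # (ny, nz, 4)
    if axis == "y":  # plane over (z, x)
        return rgba[:, k, :, :]  # (nz, nx, 4)
    return rgba[k, :, :, :].transpose(1, 0, 2)  # z: (nx, ny, 4)


def build_slice_sets(rgba: np.ndarray) -> tuple[SliceSet, SliceSet, SliceSet]:
    """Cut a pre-shaded RGBA voxel grid into the three orthogonal slice sets.

    For each axis there is one texture per voxel plane perpendicular to that
    axis; texel (u, v) of plane k carries exactly the RGBA of the
    corresponding voxel (no resampling).
    """
    rgba = np.asarray(rgba, dtype=np.float64)
    if rgba.ndim != 4 or rgba.shape[3] != 4 or min(rgba.shape[:3]) < 1:
        raise ValidationError("rgba grid must have shape (nz, ny, nx, 4), non-empty")
    nz, ny, nx, _ = rgba.shape
    sets = []
    for axis, n in zip(AXES, (nx, ny, nz)):
        textures = [
            TextureImage.from_array(_plane(rgba, axis, k)) for k in range(n)
        ]
        sets.append(SliceSet(axis, textures))
    return tuple(sets)  # type: ignore[return-value]


def default_opacity_factors(dims: tuple[int, int, int]) -> tuple[float, float, float]:
    """Axis-length-ratio starting factors (n_ref/nx, n_ref/ny, n_ref/nz).

    n_ref is the largest dimension, so the longest axis keeps factor 1 and
    shorter axes get boosted opacity.
    """
    n_ref = max(dims)
    return tuple(n_ref / d for d in dims)  # type: ignore[return-value]


def rescale_opacity(
    sets: Sequence[SliceSet],
    factors: Sequence[float] | None = None,
    dims: tuple[int, int, int] | None = None,
    linear: bool = False,
) -> list[SliceSet]:
    """Equalize composited opacity across the three slice sets.

    Per-texel rescaling ``a' = 1 - (1-a)^f`` (exponent form: under
    source-over compositing n slices of alpha a accumulate to
    ``1-(1-a)^n``, so the factor acts as an effective slice-count ratio and
    the axis-ratio defaults equalize uniform volumes exactly).  ``linear=True``
    switches to clipped ``a' = a*f`` for comparison.  Colours are unchanged.
    """
    if factors is None:
        if dims is None:
            dims = (len(sets[0]), len(sets[1]), len(sets[2]))
        factors = default_opacity_factors(dims)
    factors = tuple(float(f) for f in factors)
    if len(factors) != len(sets):
        raise ValidationError("need one opacity factor per slice set")
    if any(f <= 0 for f in factors):
        raise ValidationError("opacity factors must be > 0")
    out = []
    for s, f in zip(sets, factors):
        textures = []
        for t in s.textures:
            px = t.pixels.astype(np.float64) / 255.0
            a = px[:, :, 3]
            a2 = np.clip(a * f, 0.0, 1.0) if linear else 1.0 - (1.0 - a) ** f
            px[:, :, 3] = a2
            textures.append(TextureImage(np.round(px * 255).astype(np.uint8)))
        out.append(SliceSet(s.axis, textures, s.opacity_factor * f))
    return out


def select_slice_set(direction: Sequence[float]) -> str:
    """Pick the slice set to show for a camera view direction.

    Returns the axis whose unit vector has the greatest |dot| with the view
    direction (e.g. a view along x shows the ZY slice set).  Ties break
    x < y < z; the choice is invariant under direction negation.
    """
    d = np.asarray(direction, dtype=np.float64)
    if d.shape != (3,) or not np.all(np.isfinite(d)):
        raise ValidationError("view direction must be a finite 3-vector")
    n = np.linalg.norm(d)
    if n == 0:
        raise ValidationError("view direction must be non-zero")
    return AXES[int(np.argmax(np.abs(d / n)))]


def composite_slices(sliceset: SliceSet, front_to_back: bool = False) -> TextureImage:
    """Orthographic axis-aligned composite of a slice set (test oracle).

    Source-over operator applied back to front:
    ``C <- C_src*a_src + C*(1-a_src)``, ``A <- a_src + A*(1-a_src)``, with
    colour channels kept non-premultiplied in the accumulator.
    """
    if len(sliceset) == 0:
        raise ValidationError("cannot composite an empty slice set")
    # textures are stored in ascending axis coordinate; viewing down the axis
    # the last texture is nearest, so stored order is already back-to-front
    seq = list(reversed(sliceset.textures)) if front_to_back else sliceset.textures
    acc = np.zeros(seq[0].pixels.shape[:2] + (4,), dtype=np.float64)
    for t in seq:
        px = t.pixels.astype(np.float64) / 255.0
        a = px[:, :, 3:4]
        acc[:, :, :3] = px[:, :, :3] * a + acc[:, :, :3] * (1 - a)
        acc[:, :, 3:4] = a + acc[:, :, 3:4] * (1 - a)
    return TextureImage(np.round(np.clip(acc, 0, 1) * 255).astype(np.uint8))
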