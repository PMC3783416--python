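"""High-level assembly: data -> model tree -> Figure3D -> PDF bytes.

This module glues the pipeline stages together the way the command-line
utilities use them: volumes become three slice-set groups of textured quads,
surface soups become per-colour indexed-mesh groups, a poster is rendered,
views and the controls script are attached, and the scene is serialized and
embedded.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from PIL import Image, ImageDraw

from .errors import ValidationError
from .mesh_compress import CompressionStats, group_facets_by_colour
from .mesh_io import FacetSoup
from .pdfwriter import Figure3D, embed_pdf
from .prc import write_prc
from .scene import GeometryPayload, ModelTree
from .texture import TextureImage, savings_ratio, encode_texture
from .views import ViewPreset, default_presets, keyboard_controls_script
from .volume import (
    SliceSet,
    TransferFunction,
    Volume,
    apply_transfer,
    build_slice_sets,
    composite_slices,
    rescale_opacity,
)

#: Group short names used for the three slice sets, by axis.
SLICE_GROUP_NAMES = {"x": "VRSETX", "y": "VRSETY", "z": "VRSETZ"}


@dataclass
class PipelineStats:
    """Per-stage counters logged to stderr and exposed via --stats-json."""

    compression: CompressionStats = field(default_factory=CompressionStats)
    slice_textures: int = 0
    texture_bytes: int = 0
    texture_savings: list[float] = field(default_factory=list)
    payload_bytes: int = 0

    def log(self, file=sys.stderr) -> None:
        c = self.compression
        print(
            f"facets in: {c.facets_in}  meshes out: {c.meshes_out}  "
            f"vertex records: {c.records_before} -> {c.records_after}",
            file=file,
        )
        if self.texture_savings:
            mean = sum(self.texture_savings) / len(self.texture_savings)
            print(
                f"slice textures: {self.slice_textures}  "
                f"encoded bytes: {self.texture_bytes}  "
                f"mean savings vs raw 32bpp: {mean:.1%}",
                file=file,
            )
        print(f"scene payload bytes: {self.payload_bytes}", file=file)

    def as_dict(self) -> dict:
        c = self.compression
        return {
            "facets_in": c.facets_in,
            "meshes_out": c.meshes_out,
            "vertex_records_before": c.records_before,
            "vertex_records_after": c.records_after,
            "slice_textures": self.slice_textures,
            "texture_bytes": self.texture_bytes,
            "mean_texture_savings": (
                sum(self.texture_savings) / len(self.texture_savings)
                if self.texture_savings
                else None
            ),
            "payload_bytes": self.payload_bytes,
        }


# -- scene assembly -----------------------------------------------------------


def _slice_quad(axis: str, k: int, dims, spacing) -> np.ndarray:
    """World-space quad for slice plane k along *axis* (volume at origin)."""
    nx, ny, nz = dims
    dx, dy, dz = spacing
    ex, ey, ez = nx * dx, ny * dy, nz * dz
    if axis == "x":
        x = (k + 0.5) * dx
        return np.array([[x, 0, 0], [x, ey, 0], [x, ey, ez], [x, 0, ez]])
    if axis == "y":
        y = (k + 0.5) * dy
        return np.array([[0, y, 0], [0, y, ez], [ex, y, ez], [ex, y, 0]])
    z = (k + 0.5) * dz
    return np.array([[0, 0, z], [ex, 0, z], [ex, ey, z], [0, ey, z]])


def add_slice_sets_to_tree(
    tree: ModelTree,
    sets: Sequence[SliceSet],
    dims: tuple[int, int, int],
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    stats: PipelineStats | None = None,
) -> dict[str, str]:
    """Add the three slice sets as named groups of textured quads.

    Returns the map axis -> full group name (what view/JavaScript code uses
    to switch the displayed set).
    """
    names = {}
    for s in sets:
        full = tree.register_group(SLICE_GROUP_NAMES[s.axis])
        names[s.axis] = full
        for k, t in enumerate(s.textures):
            tree.add_payload(
                GeometryPayload(
                    kind="textured_facet",
                    coordinates=_slice_quad(s.axis, k, dims, spacing),
                    texture=t,
                )
            )
            if stats is not None:
                data, _tag = encode_texture(t)
                stats.slice_textures += 1
                stats.texture_bytes += len(data)
                stats.texture_savings.append(savings_ratio(t, data))
    return names


def add_surfaces_to_tree(
    tree: ModelTree,
    parts: dict[str, FacetSoup] | Sequence[tuple[str, FacetSoup]],
    colour_threshold: float = 0.05,
    stats: PipelineStats | None = None,
) -> dict[str, str]:
    """Colour-compress each named soup and add it as one group of indexed meshes.

    Returns the map part name -> full group name.
    """
    items = parts.items() if isinstance(parts, dict) else parts
    names = {}
    for name, soup in items:
        full = tree.register_group(name)
        names[name] = full
        meshes = group_facets_by_colour(
            soup,
            colour_threshold,
            stats=stats.compression if stats is not None else None,
        )
        for m in meshes:
            if m.opacity < 1.0:
                print(
                    f"warning: group {full!r} holds a transparent mesh; PDF "
                    "viewers may draw its facets unsorted (use "
                    "unstructured_facets=True for correct but slow output)",
                    file=sys.stderr,
                )
            tree.add_payload(GeometryPayload(kind="indexed_mesh", mesh=m))
    return names


def add_surfaces_unstructured(
    tree: ModelTree, parts: dict[str, FacetSoup]
) -> dict[str, str]:
    """Slow path for transparent surfaces: store raw facet lists, not meshes.

    Viewers draw unstructured transparent facets in correct depth order, at a
    heavy cost in file size and figure initialisation time.
    """
    names = {}
    for name, soup in parts.items():
        full = tree.register_group(name)
        names[name] = full
        for f in soup:
            tree.add_payload(
                GeometryPayload(
                    kind="facets",
                    coordinates=f.vertices[None, :, :],
                    colour=f.colour,
                    opacity=f.opacity,
                    normals=None if f.normal is None else f.normal[None, :],
                )
            )
    return names


# -- poster rendering ---------------------------------------------------------


def render_mesh_poster(
    parts: dict[str, FacetSoup],
    size: tuple[int, int] = (512, 512),
    view_dir: Sequence[float] = (1.0, 1.0, 1.0),
) -> TextureImage:
    """Simple orthographic flat-shaded raster of the surfaces (poster image).

    Painter's algorithm: facets are depth-sorted along *view_dir* and filled
    back to front with their colour scaled by a Lambert term against a
    headlight.  Good enough for a static preview; not a faithful render.
    """
    all_facets = [f for soup in parts.values() for f in soup]
    if not all_facets:
        raise ValidationError("no facets to render")
    d = np.asarray(view_dir, dtype=np.float64)
    d = d / np.linalg.norm(d)
    up0 = np.array([0.0, 0.0, 1.0])
    if abs(float(np.dot(d, up0))) > 0.999:
        up0 = np.array([0.0, 1.0, 0.0])
    right = np.cross(d, up0)
    right /= np.linalg.norm(right)
    up = np.cross(right, d)

    pts = np.concatenate([f.vertices for f in all_facets])
    u = pts @ right
    v = pts @ up
    margin = 0.05
    u0, u1 = u.min(), u.max()
    v0, v1 = v.min(), v.max()
    span = max(u1 - u0, v1 - v0, 1e-12) * (1 + 2 * margin)
    cu, cv = (u0 + u1) / 2, (v0 + v1) / 2
    w, h = size

    img = Image.new("RGB", size, (255, 255, 255))
    draw = ImageDraw.Draw(img)
    order = sorted(
        all_facets, key=lambda f: float(np.mean(f.vertices @ d)), reverse=True
    )
    for f in order:
        fu = (f.vertices @ right - cu) / span + 0.5
        fv = (f.vertices @ up - cv) / span + 0.5
        poly = [(float(x) * (w - 1), float((1 - y)) * (h - 1)) for x, y in zip(fu, fv)]
        e1 = f.vertices[1] - f.vertices[0]
        e2 = f.vertices[2] - f.vertices[0]
        n = np.cross(e1, e2)
        nn = np.linalg.norm(n)
        lambert = abs(float(np.dot(n / nn, d))) if nn > 0 else 1.0
        shade = 0.25 + 0.75 * lambert
        colour = tuple(int(round(255 * c * shade)) for c in f.colour)
        draw.polygon(poly, fill=colour)
    return TextureImage.from_array(np.asarray(img))


def render_volume_poster(sets: Sequence[SliceSet], axis: str = "z") -> TextureImage:
    """Poster for a volume figure: orthographic composite of one slice set
    over a white background."""
    for s in sets:
        if s.axis == axis:
            comp = composite_slices(s)
            px = comp.pixels.astype(np.float64) / 255.0
            a = px[:, :, 3:4]
            rgb = px[:, :, :3] * a + 1.0 * (1 - a)
            return TextureImage.from_array(rgb)
    raise ValidationError(f"no slice set for axis {axis!r}")


# -- figure assembly ----------------------------------------------------------


def make_figure(
    tree: ModelTree,
    poster: TextureImage,
    presets: Sequence[ViewPreset] | None = None,
    script: str | None = None,
    activation: str = "click",
    stats: PipelineStats | None = None,
) -> Figure3D:
    """Serialize the tree and wrap everything into a Figure3D."""
    payload = write_prc(tree)
    if stats is not None:
        stats.payload_bytes = len(payload.bytes)
    return Figure3D(
        prc=payload,
        poster=poster,
        presets=list(presets) if presets is not None else default_presets(),
        script=script if script is not None else keyboard_controls_script(),
        activation=activation,
    )


def volume_to_figure(
    volume: Volume,
    tf: TransferFunction | None = None,
    opacity_factors: Sequence[float] | None = None,
    subsample: int | Sequence[int] = 1,
    surfaces: dict[str, FacetSoup] | None = None,
    presets: Sequence[ViewPreset] | None = None,
    activation: str = "click",
    colour_threshold: float = 0.05,
    stats: PipelineStats | None = None,
) -> Figure3D:
    """Full volume path: transfer function, slice sets, equalization, figure.

    Optional *surfaces* are overlaid in the same world coordinate system
    (volume voxel index * spacing).  Default opacity factors are the
    axis-length ratios; pass explicit factors to hand-tune the equalization.
    """
    vol = volume.subsample(subsample) if subsample not in (1, (1, 1, 1)) else volume
    tf = tf or TransferFunction()
    rgba = apply_transfer(vol, tf)
    sets = build_slice_sets(rgba)
    sets = rescale_opacity(sets, opacity_factors, dims=vol.dims)
    tree = ModelTree()
    add_slice_sets_to_tree(tree, sets, vol.dims, vol.spacing, stats=stats)
    if surfaces:
        add_surfaces_to_tree(tree, surfaces, colour_threshold, stats=stats)
    poster = render_volume_poster(sets)
    return make_figure(tree, poster, presets, activation=activation, stats=stats)


def surfaces_to_figure(
    parts: dict[str, FacetSoup],
    presets: Sequence[ViewPreset] | None = None,
    activation: str = "click",
    colour_threshold: float = 0.05,
    unstructured_transparent: bool = False,
    stats: PipelineStats | None = None,
) -> Figure3D:
    """Surface path: colour compression, indexed meshes, poster, figure."""
    tree = ModelTree()
    if unstructured_transparent:
        opaque = {n: s for n, s in parts.items() if all(f.opacity == 1.0 for f in s)}
        transparent = {n: s for n, s in parts.items() if n not in opaque}
        if opaque:
            add_surfaces_to_tree(tree, opaque, colour_threshold, stats=stats)
        if transparent:
            add_surfaces_unstructured(tree, transparent)
    else:
        add_surfaces_to_tree(tree, parts, colour_threshold, stats=stats)
    poster = render_mesh_poster(parts)
    return make_figure(tree, poster, presets, activation=activation, stats=stats)


def figure_to_pdf(fig: Figure3D) -> bytes:
    return embed_pdf(fig)
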