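"""Deterministic synthetic volumes and meshes for tests and examples.

Every generator is a pure function of its :class:`FixtureSpec` (seeded where
randomness is involved), so identical specs yield byte-identical outputs.
The volume kinds emulate the intensity structure of real acquisitions —
a centred Gaussian blob (soft-tissue-like bright core) and a spherical shell
(a bright surface such as a vessel wall or skull) — while the mesh kinds
(uv-sphere, torus, two-part anatomy) stand in for segmented anatomical
surfaces.  None of them reproduce acquisition noise, scanner anisotropy or
segmentation artefacts of real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .mesh_io import Facet, FacetSoup
from .volume import INTENSITY_MAX, Volume

VOLUME_KINDS = ("gaussian_blob", "spherical_shell")
MESH_KINDS = ("uv_sphere_mesh", "torus_mesh", "two_part_anatomy")


@dataclass
class FixtureSpec:
    """Recipe for one synthetic fixture.

    ``size`` parameters by kind: volumes take ``dims`` (nx, ny, nz) and
    ``radius`` / ``sigma`` in voxels; meshes take ``radius`` (+ ``tube_radius``
    for the torus) in world units and ``segments`` (latitude/longitude or
    major/minor subdivision count).
    """

    kind: str
    seed: int = 0
    dims: tuple[int, int, int] = (33, 33, 33)
    sigma: float = 6.0
    radius: float = 10.0
    tube_radius: float = 0.35
    segments: int = 16
    noise: float = 0.0
    params: dict = field(default_factory=dict)


def _coords(dims: tuple[int, int, int]):
    nx, ny, nz = dims
    z, y, x = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    return x - cx, y - cy, z - cz


def synth_volume(spec: FixtureSpec) -> Volume:
    """Generate a deterministic synthetic volume.

    ``gaussian_blob`` peaks at the centre voxel; ``spherical_shell`` has its
    maximum intensity on the stated radius.  Optional additive uniform noise
    of amplitude ``spec.noise`` (fraction of full scale) is seeded.
    """
    if spec.kind not in VOLUME_KINDS:
        raise ValidationError(
            f"unknown volume kind {spec.kind!r}; known: {VOLUME_KINDS}"
        )
    if min(spec.dims) < 1:
        raise ValidationError("volume dims must be >= 1")
    dx, dy, dz = _coords(spec.dims)
    r = np.sqrt(dx**2 + dy**2 + dz**2)
    if spec.kind == "gaussian_blob":
        if spec.sigma <= 0:
            raise ValidationError("sigma must be > 0")
        field_ = np.exp(-(r**2) / (2 * spec.sigma**2))
    else:
        if spec.radius <= 0:
            raise ValidationError("radius must be > 0")
        shell_width = max(spec.radius / 8.0, 1.0)
        field_ = np.exp(-((r - spec.radius) ** 2) / (2 * shell_width**2))
    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        field_ = np.clip(field_ + rng.uniform(0, spec.noise, field_.shape), 0, None)
        field_ = field_ / field_.max()
    return Volume(np.round(field_ * INTENSITY_MAX).astype(np.uint16))


def _uv_sphere(radius: float, segments: int, colour, centre=(0.0, 0.0, 0.0)) -> FacetSoup:
    if radius <= 0 or segments < 3:
        raise ValidationError("uv sphere needs radius > 0 and segments >= 3")
    nlat = nlon = segments
    cx, cy, cz = centre
    verts = np.empty((nlat + 1, nlon, 3))
    for i in range(nlat + 1):
        theta = np.pi * i / nlat
        for j in range(nlon):
            phi = 2 * np.pi * j / nlon
            verts[i, j] = (
                cx + radius * np.sin(theta) * np.cos(phi),
                cy + radius * np.sin(theta) * np.sin(phi),
                cz + radius * np.cos(theta),
            )
    facets = []
    for i in range(nlat):
        for j in range(nlon):
            j2 = (j + 1) % nlon
            a, b = verts[i, j], verts[i, j2]
            c, d = verts[i + 1, j2], verts[i + 1, j]
            if i == 0:  # pole caps collapse to triangles
                facets.append(Facet(np.array([a, c, d]), None, colour))
            elif i == nlat - 1:
                facets.append(Facet(np.array([a, b, c]), None, colour))
            else:
                facets.append(Facet(np.array([a, b, c]), None, colour))
                facets.append(Facet(np.array([a, c, d]), None, colour))
    return FacetSoup(facets)


def _torus(radius: float, tube: float, segments: int, colour) -> FacetSoup:
    if radius <= 0 or tube <= 0 or segments < 3:
        raise ValidationError("torus needs positive radii and segments >= 3")
    n = segments
    facets = []

    def point(i, j):
        # index modulo n so wrap-around vertices are bitwise identical
        u = 2 * np.pi * (i % n) / n
        v = 2 * np.pi * (j % n) / n
        return np.array(
            [
                (radius + tube * np.cos(v)) * np.cos(u),
                (radius + tube * np.cos(v)) * np.sin(u),
                tube * np.sin(v),
            ]
        )

    for i in range(n):
        for j in range(n):
            a = point(i, j)
            b = point(i + 1, j)
            c = point(i + 1, j + 1)
            d = point(i, j + 1)
            facets.append(Facet(np.array([a, b, c]), None, colour))
            facets.append(Facet(np.array([a, c, d]), None, colour))
    return FacetSoup(facets)


def synth_mesh(spec: FixtureSpec) -> dict[str, FacetSoup]:
    """Generate deterministic synthetic surfaces as named parts.

    Returns a mapping of part name to facet soup: one entry for
    ``uv_sphere_mesh`` / ``torus_mesh``, two (``shell`` + ``core``, at
    different radii and colours) for ``two_part_anatomy``.
    """
    if spec.kind not in MESH_KINDS:
        raise ValidationError(f"unknown mesh kind {spec.kind!r}; known: {MESH_KINDS}")
    if spec.kind == "uv_sphere_mesh":
        return {"sphere": _uv_sphere(spec.radius, spec.segments, (0.8, 0.8, 0.8))}
    if spec.kind == "torus_mesh":
        return {
            "torus": _torus(
                spec.radius, spec.tube_radius * spec.radius, spec.segments, (0.8, 0.5, 0.2)
            )
        }
    return {
        "shell": _uv_sphere(spec.radius, spec.segments, (0.9, 0.9, 0.8)),
        "core": _uv_sphere(spec.radius * 0.45, max(spec.segments // 2, 3), (0.8, 0.2, 0.2)),
    }
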