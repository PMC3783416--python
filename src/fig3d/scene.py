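"""Named hierarchical model tree for 3-d figure export.

The model tree is the organising structure of an exportable 3-d scene: named
groups (which a PDF viewer presents as toggleable branches of the figure's
model tree) containing geometry payloads.  Group names given by the caller are
made globally unique by appending a 1-based decimal serial per short name
("cortex" -> "cortex1", "cortex2", ...), and the short->full mapping can be
written to a companion node-map text file (``s2direct.map``) so that views
files and scripts can address nodes by their full names.

Billboards — textured quads that always face the camera — are stored as
ordinary payloads; :func:`orient_billboards` computes the per-quad rigid
transform that turns each one toward a given camera position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .errors import ParseError, ValidationError

PAYLOAD_KINDS = frozenset(
    {"points", "lines", "facets", "indexed_mesh", "textured_facet", "billboard"}
)

#: Name of the implicit root group that receives payloads added before any
#: register_group call.
ROOT_GROUP_NAME = "S2ROOT"


@dataclass
class GeometryPayload:
    """A leaf of the model tree: one batch of geometry of a single kind.

    Parameters
    ----------
    kind:
        One of ``points``, ``lines``, ``facets``, ``indexed_mesh``,
        ``textured_facet`` or ``billboard``.
    coordinates:
        World-unit vertex data.  For ``facets``/``textured_facet``/``billboard``
        an array of shape (nfacet, 3 or 4, 3); for ``points`` (n, 3); for
        ``lines`` (nseg, 2, 3).  ``indexed_mesh`` payloads instead carry the
        mesh object in :attr:`mesh`.
    colour:
        RGB triple in [0, 1].
    opacity:
        Scalar opacity in [0, 1].
    texture:
        Optional texture image (``fig3d.texture.TextureImage``) for textured
        facets and billboards.
    normals:
        Optional per-facet normals, shape (nfacet, 3).
    mesh:
        Optional ``fig3d.mesh_compress.IndexedMesh`` for ``indexed_mesh``.
    """

    kind: str
    coordinates: Optional[np.ndarray] = None
    colour: tuple[float, float, float] = (1.0, 1.0, 1.0)
    opacity: float = 1.0
    texture: object = None
    normals: Optional[np.ndarray] = None
    mesh: object = None

    def __post_init__(self) -> None:
        if self.kind not in PAYLOAD_KINDS:
            raise ValidationError(f"unknown payload kind: {self.kind!r}")
        if self.coordinates is not None:
            self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
            if not np.all(np.isfinite(self.coordinates)):
                raise ValidationError("payload coordinates must be finite")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=np.float64)
            if not np.all(np.isfinite(self.normals)):
                raise ValidationError("payload normals must be finite")
        c = tuple(float(v) for v in self.colour)
        if len(c) != 3 or any(v < 0 or v > 1 for v in c):
            raise ValidationError("colour must be RGB in [0,1]")
        self.colour = c
        if not (0.0 <= float(self.opacity) <= 1.0):
            raise ValidationError("opacity must lie in [0,1]")
        if self.kind == "billboard":
            if self.coordinates is None or self.coordinates.shape[-2:] != (4, 3):
                raise ValidationError("billboard payloads are 4-vertex facets")
            if self.texture is None:
                raise ValidationError("billboard payloads require a texture")


@dataclass
class Group:
    """A named node of the model tree."""

    short_name: str
    full_name: str
    payloads: list[GeometryPayload] = field(default_factory=list)
    children: list["Group"] = field(default_factory=list)


class ModelTree:
    """Ordered, named scene graph with a single implicit root group.

    Groups registered via :meth:`register_group` become children of the root,
    and the most recently registered group is "current": payloads added with
    :meth:`add_payload` attach to it (or to the root if nothing was registered
    yet), mirroring the push-name/draw idiom of scene-graph exporters.
    """

    def __init__(self) -> None:
        self._serials: dict[str, int] = {}
        self.root = Group(ROOT_GROUP_NAME, self._make_full(ROOT_GROUP_NAME))
        self._current = self.root

    # -- names ---------------------------------------------------------------

    def _make_full(self, short: str) -> str:
        serial = self._serials.get(short, 0) + 1
        self._serials[short] = serial
        return f"{short}{serial}"

    def register_group(self, name: str, parent: Optional[Group] = None) -> str:
        """Create a new named group and make it current.

        Returns the unique full name (short name + decimal serial suffix).
        """
        if not isinstance(name, str) or not name or not name.strip():
            raise ValidationError("group name must be a non-empty string")
        if not name.isprintable() or any(ch.isspace() for ch in name):
            raise ValidationError(f"group name must be printable, no whitespace: {name!r}")
        group = Group(name, self._make_full(name))
        (parent or self.root).children.append(group)
        self._current = group
        return group.full_name

    # -- payloads ------------------------------------------------------------

    @property
    def current_group(self) -> Group:
        return self._current

    def add_payload(self, payload: GeometryPayload) -> None:
        """Append *payload* to the current group (root if none registered)."""
        if not isinstance(payload, GeometryPayload):
            raise ValidationError("payload must be a GeometryPayload")
        self._current.payloads.append(payload)

    # -- queries -------------------------------------------------------------

    def walk(self) -> Iterator[tuple[Group, tuple[str, ...]]]:
        """Yield (group, dotted-path components) in depth-first pre-order."""

        def rec(g: Group, path: tuple[str, ...]) -> Iterator[tuple[Group, tuple[str, ...]]]:
            yield g, path
            for child in g.children:
                yield from rec(child, path + (child.full_name,))

        yield from rec(self.root, (self.root.full_name,))

    def groups(self) -> list[Group]:
        return [g for g, _ in self.walk()]

    def full_names(self) -> list[str]:
        return [g.full_name for g in self.groups()]

    def resolve(self, full_name: str) -> Group:
        """Find the group with the given full name (unique by construction)."""
        for g in self.groups():
            if g.full_name == full_name:
                return g
        raise KeyError(full_name)

    def resolve_path(self, dotted: str) -> Group:
        """Resolve a dotted full-name path from the root, e.g. ``S2ROOT1.cortex1``."""
        parts = dotted.split(".")
        if not parts or parts[0] != self.root.full_name:
            raise KeyError(dotted)
        g = self.root
        for part in parts[1:]:
            for child in g.children:
                if child.full_name == part:
                    g = child
                    break
            else:
                raise KeyError(dotted)
        return g


# -- node map (s2direct.map) -------------------------------------------------


def write_node_map(tree: ModelTree) -> str:
    """Serialize the short->full-dotted-path map for every named group.

    One line per group below the root: ``short<TAB>full.dotted.path``, LF
    endings.  The root itself is not listed (it carries no caller-given name).
    """
    lines = []
    for group, path in tree.walk():
        if group is tree.root:
            continue
        lines.append(f"{group.short_name}\t{'.'.join(path)}")
    return "".join(line + "\n" for line in lines)


def parse_node_map(text: str) -> list[tuple[str, str]]:
    """Parse node-map text back to (short name, full dotted path) pairs."""
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if "\t" not in line:
            raise ParseError(f"node map line {lineno}: missing tab separator")
        short, _, path = line.partition("\t")
        if not short or not path:
            raise ParseError(f"node map line {lineno}: empty field")
        out.append((short, path))
    return out


# -- billboards ----------------------------------------------------------------


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector *a* onto unit vector *b*."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    s = float(np.linalg.norm(v))
    if s < 1e-15:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis perpendicular to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-12:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis = axis / np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / (s * s))


def quad_normal(quad: np.ndarray) -> np.ndarray:
    """Unit normal of a (near-)planar 4-vertex facet via Newell's method."""
    q = np.asarray(quad, dtype=np.float64)
    n = np.zeros(3)
    for i in range(4):
        a, b = q[i], q[(i + 1) % 4]
        n += np.cross(a, b)
    norm = np.linalg.norm(n)
    if norm < 1e-15:
        raise ValidationError("degenerate billboard quad")
    return n / norm


def orient_billboards(
    tree: ModelTree,
    camera_position: np.ndarray,
    camera_target: np.ndarray,
) -> list[tuple[GeometryPayload, np.ndarray, np.ndarray]]:
    """Compute the rigid transform turning every billboard toward the camera.

    For each billboard payload, the quad is rotated about its own centre so
    that its normal points from the centre toward ``camera_position`` (no
    roll: the minimal such rotation is used).  Returns a list of
    ``(payload, rotation 3x3, rotated quad 4x3)`` tuples; payloads are not
    modified in place.
    """
    cam = np.asarray(camera_position, dtype=np.float64)
    tgt = np.asarray(camera_target, dtype=np.float64)
    if not (np.all(np.isfinite(cam)) and np.all(np.isfinite(tgt))):
        raise ValidationError("camera position/target must be finite")
    if np.allclose(cam, tgt):
        raise ValidationError("camera position must differ from target")

    out = []
    for group in tree.groups():
        for payload in group.payloads:
            if payload.kind != "billboard":
                continue
            quad = payload.coordinates.reshape(4, 3)
            centre = quad.mean(axis=0)
            direction = cam - centre
            dn = np.linalg.norm(direction)
            if dn < 1e-15:
                raise ValidationError("camera coincides with billboard centre")
            direction = direction / dn
            rot = _rotation_between(quad_normal(quad), direction)
            rotated = (quad - centre) @ rot.T + centre
            out.append((payload, rot, rotated))
    return out
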