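"""Readers for the surface formats consumed by the figure pipeline.

Surfaces enter the pipeline as *facet soups*: flat lists of independent 3- or
4-vertex facets, each with an optional facet normal, a solid RGB colour and an
opacity.  Four formats are supported:

* STL, both ASCII (``solid`` header + facet records) and little-endian binary
  (80-byte header, uint32 facet count, 50-byte records);
* Wavefront OBJ (``v``/``vn``/``f`` records, 1-based and negative indices;
  quads kept as 4-vertex facets, larger polygons fan-triangulated);
* FreeSurfer ASCII triangle surface files (comment line, ``nvert nface``,
  vertex lines, 0-based face lines);
* FreeSurfer ASCII weight ("W") files holding sparse per-vertex scalars used
  to paint activation maps onto a surface.

Texture coordinates and material libraries in OBJ input are ignored: the
pipeline shades each surface with one nominated solid colour and transparency.
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ParseError, ValidationError

DEFAULT_COLOUR = (0.7, 0.7, 0.7)


@dataclass
class Facet:
    """One independent 3- or 4-vertex facet."""

    vertices: np.ndarray  # (3 or 4, 3) float64
    normal: Optional[np.ndarray] = None  # (3,) or None
    colour: tuple[float, float, float] = DEFAULT_COLOUR
    opacity: float = 1.0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.shape not in {(3, 3), (4, 3)}:
            raise ValidationError("facet must have 3 or 4 vertices in 3-d")
        if not np.all(np.isfinite(self.vertices)):
            raise ValidationError("facet vertices must be finite")
        if self.normal is not None:
            self.normal = np.asarray(self.normal, dtype=np.float64)
            if self.normal.shape != (3,) or not np.all(np.isfinite(self.normal)):
                raise ValidationError("facet normal must be a finite 3-vector")
        c = tuple(float(v) for v in self.colour)
        if len(c) != 3 or any(v < 0 or v > 1 for v in c):
            raise ValidationError("facet colour must be RGB in [0,1]")
        self.colour = c
        if not (0.0 <= float(self.opacity) <= 1.0):
            raise ValidationError("facet opacity must lie in [0,1]")


@dataclass
class FacetSoup:
    """Unstructured list of independent facets."""

    facets: list[Facet] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.facets)

    def __iter__(self):
        return iter(self.facets)

    def extend(self, other: "FacetSoup") -> None:
        self.facets.extend(other.facets)


@dataclass
class VertexWeights:
    """Sparse per-vertex scalar weights; unlisted vertices weigh 0."""

    weights: dict[int, float] = field(default_factory=dict)

    def __getitem__(self, index: int) -> float:
        return self.weights.get(index, 0.0)

    def __len__(self) -> int:
        return len(self.weights)


# -- STL ----------------------------------------------------------------------


def _read_stl_ascii(text: str, colour, opacity) -> FacetSoup:
    facets: list[Facet] = []
    normal: Optional[np.ndarray] = None
    verts: list[list[float]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        tok = raw.split()
        if not tok:
            continue
        key = tok[0].lower()
        try:
            if key == "facet" and len(tok) >= 5 and tok[1].lower() == "normal":
                normal = np.array([float(v) for v in tok[2:5]])
                verts = []
            elif key == "vertex":
                verts.append([float(v) for v in tok[1:4]])
            elif key == "endfacet":
                if len(verts) != 3:
                    raise ParseError(f"STL line {lineno}: facet with {len(verts)} vertices")
                facets.append(Facet(np.array(verts), normal, colour, opacity))
                normal, verts = None, []
        except (ValueError, IndexError) as exc:
            raise ParseError(f"STL line {lineno}: {raw.strip()!r}") from exc
    return FacetSoup(facets)


def _read_stl_binary(data: bytes, colour, opacity) -> FacetSoup:
    if len(data) < 84:
        raise ParseError("binary STL shorter than header + count")
    (count,) = struct.unpack_from("<I", data, 80)
    need = 84 + 50 * count
    if len(data) < need:
        raise ParseError(
            f"binary STL truncated: declares {count} facets, payload holds "
            f"{(len(data) - 84) // 50}"
        )
    facets = []
    for i in range(count):
        rec = struct.unpack_from("<12fH", data, 84 + 50 * i)
        normal = np.array(rec[0:3])
        verts = np.array(rec[3:12]).reshape(3, 3)
        if not np.all(np.isfinite(verts)):
            raise ParseError(f"binary STL facet {i}: non-finite vertex")
        facets.append(Facet(verts, normal, colour, opacity))
    return FacetSoup(facets)


def read_stl(
    data: bytes | str,
    colour: Sequence[float] = DEFAULT_COLOUR,
    opacity: float = 1.0,
) -> FacetSoup:
    """Read an ASCII or binary STL stream into a facet soup.

    The format is auto-detected: a stream is ASCII if it starts with ``solid``
    and contains a ``facet`` keyword (binary files may also start with
    "solid" in their free-form header).  Facet normals are taken from the
    file; the given solid *colour* and *opacity* are applied to every facet.
    """
    colour = tuple(float(v) for v in colour)
    if isinstance(data, str):
        return _read_stl_ascii(data, colour, opacity)
    head = data[:512]
    if head.lstrip().startswith(b"solid"):
        try:
            text = data.decode("ascii")
        except UnicodeDecodeError:
            text = None
        if text is not None and "facet" in text:
            return _read_stl_ascii(text, colour, opacity)
    return _read_stl_binary(data, colour, opacity)


def write_stl_ascii(soup: FacetSoup, name: str = "fig3d") -> str:
    """Serialize a triangle soup as ASCII STL (quads are rejected)."""
    out = io.StringIO()
    out.write(f"solid {name}\n")
    for f in soup:
        if f.vertices.shape[0] != 3:
            raise ValidationError("STL stores triangles only")
        n = f.normal if f.normal is not None else np.zeros(3)
        out.write(f"  facet normal {n[0]:g} {n[1]:g} {n[2]:g}\n")
        out.write("    outer loop\n")
        for v in f.vertices:
            out.write(f"      vertex {v[0]:g} {v[1]:g} {v[2]:g}\n")
        out.write("    endloop\n  endfacet\n")
    out.write(f"endsolid {name}\n")
    return out.getvalue()


def write_stl_binary(soup: FacetSoup) -> bytes:
    """Serialize a triangle soup as little-endian binary STL."""
    buf = io.BytesIO()
    buf.write(b"\0" * 80)
    buf.write(struct.pack("<I", len(soup)))
    for f in soup:
        if f.vertices.shape[0] != 3:
            raise ValidationError("STL stores triangles only")
        n = f.normal if f.normal is not None else np.zeros(3)
        buf.write(struct.pack("<12fH", *n, *f.vertices.reshape(-1), 0))
    return buf.getvalue()


# -- OBJ ----------------------------------------------------------------------


def _obj_index(token: str, n: int, lineno: int) -> int:
    """Resolve an OBJ face index token ('3', '3/1', '3//2', '-1') to 0-based."""
    idx_str = token.split("/", 1)[0]
    try:
        idx = int(idx_str)
    except ValueError as exc:
        raise ParseError(f"OBJ line {lineno}: bad face index {token!r}") from exc
    if idx == 0:
        raise ParseError(f"OBJ line {lineno}: face index 0 is invalid")
    resolved = idx - 1 if idx > 0 else n + idx
    if not (0 <= resolved < n):
        raise ParseError(f"OBJ line {lineno}: face index {idx} out of range (nv={n})")
    return resolved


def read_obj(
    text: str,
    colour: Sequence[float] = DEFAULT_COLOUR,
    opacity: float = 1.0,
) -> FacetSoup:
    """Read a Wavefront OBJ stream into a facet soup.

    Triangles and quads are preserved as 3-/4-vertex facets; faces with more
    than 4 vertices are fan-triangulated from the first vertex.  Vertex
    normals, texture coordinates and materials are ignored; every facet gets
    the nominated solid colour and opacity.
    """
    colour = tuple(float(v) for v in colour)
    vertices: list[list[float]] = []
    facets: list[Facet] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        if tok[0] == "v":
            try:
                vertices.append([float(v) for v in tok[1:4]])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"OBJ line {lineno}: bad vertex") from exc
            if not np.all(np.isfinite(vertices[-1])):
                raise ParseError(f"OBJ line {lineno}: non-finite vertex")
        elif tok[0] == "f":
            idx = [_obj_index(t, len(vertices), lineno) for t in tok[1:]]
            if len(idx) < 3:
                raise ParseError(f"OBJ line {lineno}: face with <3 vertices")
            varr = np.asarray(vertices)
            if len(idx) <= 4:
                facets.append(Facet(varr[idx], None, colour, opacity))
            else:  # fan-triangulate >4-gons from the first vertex
                for k in range(1, len(idx) - 1):
                    tri = [idx[0], idx[k], idx[k + 1]]
                    facets.append(Facet(varr[tri], None, colour, opacity))
        # vn/vt/usemtl/mtllib/o/g/s silently ignored
    return FacetSoup(facets)


def write_obj(soup: FacetSoup) -> str:
    """Serialize a facet soup as OBJ (unshared vertices, one face per facet)."""
    verts: list[str] = []
    faces: list[str] = []
    count = 0
    for f in soup:
        idx = []
        for v in f.vertices:
            verts.append(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
            count += 1
            idx.append(count)
        faces.append("f " + " ".join(str(i) for i in idx))
    return "\n".join(verts + faces) + "\n"


# -- FreeSurfer ASCII surface -------------------------------------------------


def read_fs_surface(
    text: str,
    colour: Sequence[float] = DEFAULT_COLOUR,
    opacity: float = 1.0,
) -> tuple[FacetSoup, np.ndarray, np.ndarray]:
    """Read a FreeSurfer ASCII triangle surface file.

    Layout: a first comment line, then ``<nvert> <nface>``, then ``nvert``
    lines ``x y z flag``, then ``nface`` lines ``i j k flag`` with 0-based
    vertex indices.  Returns ``(soup, vertices (nvert,3), faces (nface,3))``
    so that per-vertex weights can be mapped back onto the surface.
    """
    colour = tuple(float(v) for v in colour)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise ParseError("FreeSurfer surface: missing header lines")
    try:
        nvert, nface = (int(v) for v in lines[1].split()[:2])
    except (ValueError, IndexError) as exc:
        raise ParseError("FreeSurfer surface: bad count line") from exc
    if len(lines) != 2 + nvert + nface:
        raise ParseError(
            f"FreeSurfer surface: {nvert}+{nface} records declared, "
            f"{len(lines) - 2} lines present"
        )
    try:
        verts = np.array(
            [[float(v) for v in lines[2 + i].split()[:3]] for i in range(nvert)]
        ).reshape(nvert, 3)
        faces = np.array(
            [[int(v) for v in lines[2 + nvert + i].split()[:3]] for i in range(nface)],
            dtype=np.int64,
        ).reshape(nface, 3)
    except (ValueError, IndexError) as exc:
        raise ParseError("FreeSurfer surface: malformed record") from exc
    if not np.all(np.isfinite(verts)):
        raise ParseError("FreeSurfer surface: non-finite vertex")
    if nface and (faces.min() < 0 or faces.max() >= nvert):
        raise ParseError("FreeSurfer surface: face index out of range")
    soup = FacetSoup([Facet(verts[f], None, colour, opacity) for f in faces])
    return soup, verts, faces


def write_fs_surface(verts: np.ndarray, faces: np.ndarray, comment: str = "#!ascii") -> str:
    verts = np.asarray(verts, dtype=np.float64)
    faces = np.asarray(faces, dtype=np.int64)
    out = [comment, f"{len(verts)} {len(faces)}"]
    out += [f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g} 0" for v in verts]
    out += [f"{f[0]} {f[1]} {f[2]} 0" for f in faces]
    return "\n".join(out) + "\n"


# -- FreeSurfer ASCII weight files -------------------------------------------


def read_fs_weights(text: str, vertex_bound: Optional[int] = None) -> VertexWeights:
    """Read a FreeSurfer ASCII weight ("W") file into sparse vertex weights.

    Dialect used here: line 1 is an ignored scalar (latency field), line 2 is
    the pair count ``n``, then ``n`` lines of ``vertexIndex value``.  Vertices
    not listed carry weight 0.  If *vertex_bound* is given, indices must be
    below it.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise ParseError("weight file: missing header lines")
    try:
        count = int(lines[1].split()[0])
    except (ValueError, IndexError) as exc:
        raise ParseError("weight file: bad count line") from exc
    if count < 0 or len(lines) != 2 + count:
        raise ParseError(
            f"weight file: {count} pairs declared, {len(lines) - 2} present"
        )
    weights: dict[int, float] = {}
    for i in range(count):
        tok = lines[2 + i].split()
        try:
            idx, val = int(tok[0]), float(tok[1])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"weight file: malformed pair on line {3 + i}") from exc
        if idx < 0:
            raise ParseError(f"weight file: negative vertex index {idx}")
        if vertex_bound is not None and idx >= vertex_bound:
            raise ParseError(
                f"weight file: vertex index {idx} >= bound {vertex_bound}"
            )
        if not np.isfinite(val):
            raise ParseError("weight file: non-finite weight")
        weights[idx] = val
    return VertexWeights(weights)


def write_fs_weights(w: VertexWeights) -> str:
    lines = ["0", str(len(w.weights))]
    lines += [f"{i} {v:.9g}" for i, v in sorted(w.weights.items())]
    return "\n".join(lines) + "\n"
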