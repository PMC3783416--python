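"""Compact binary scene container embedded as the 3-d stream of a PDF figure.

The container mirrors the structure of the PRC (Product Representation
Compact) scene format consumed by 3-d-capable PDF viewers — a named assembly
tree whose leaves are tessellated entities (point sets, polylines, indexed
meshes, textured facets) — for exactly the entity subset this package emits.
No public reference implementation of a PRC reader exists, so conformance of
the byte stream to external consumers cannot be machine-checked; the
authoritative automated contract is therefore the in-repo round trip:
:func:`read_prc` reconstructs a scene structurally equal to the source (group
names and order, entity counts, colours exact; coordinates to float32;
texture streams byte-equal).  The payload is deterministic: identical input
scenes yield identical bytes.

Layout: an 8-byte magic, a little-endian uint32 length of the zlib-compressed
body, then the body — a depth-first serialization of the group tree using
length-prefixed UTF-8 strings, uint32 counts and float32 arrays.
"""

from __future__ import annotations

import hashlib
import io
import struct
import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import ParseError, ValidationError
from .mesh_compress import IndexedMesh
from .scene import GeometryPayload, Group, ModelTree
from .texture import TextureImage, decode_texture, encode_texture

MAGIC = b"PRCF3D1\n"

_KINDS = ["points", "lines", "facets", "indexed_mesh", "textured_facet", "billboard"]


@dataclass
class EncodedTexture:
    """A texture as stored in the container: encoded bytes + container tag."""

    data: bytes
    tag: str  # "jpeg" | "png"

    def digest(self) -> str:
        return hashlib.sha256(self.data).hexdigest()

    def image(self) -> TextureImage:
        return decode_texture(self.data)


@dataclass
class Manifest:
    """Index of the payload: group names, entity counts, texture digests."""

    group_names: list[str] = field(default_factory=list)
    entity_counts: dict[str, int] = field(default_factory=dict)
    texture_digests: list[str] = field(default_factory=list)


@dataclass
class PRCPayload:
    bytes: bytes
    manifest: Manifest


# -- primitive serializers ----------------------------------------------------


def _w_u32(buf: io.BytesIO, v: int) -> None:
    buf.write(struct.pack("<I", v))


def _w_str(buf: io.BytesIO, s: str) -> None:
    enc = s.encode("utf-8")
    _w_u32(buf, len(enc))
    buf.write(enc)


def _w_f32s(buf: io.BytesIO, arr: np.ndarray) -> None:
    a = np.asarray(arr, dtype="<f4")
    _w_u32(buf, a.size)
    buf.write(a.tobytes())


class _Reader:
    def __init__(self, data: bytes) -> None:
        self.data = data
        self.pos = 0

    def take(self, n: int) -> bytes:
        if self.pos + n > len(self.data):
            raise ParseError("PRC payload truncated")
        out = self.data[self.pos : self.pos + n]
        self.pos += n
        return out

    def u32(self) -> int:
        return struct.unpack("<I", self.take(4))[0]

    def f32(self) -> float:
        return struct.unpack("<f", self.take(4))[0]

    def string(self) -> str:
        return self.take(self.u32()).decode("utf-8")

    def f32s(self) -> np.ndarray:
        n = self.u32()
        return np.frombuffer(self.take(4 * n), dtype="<f4").astype(np.float64)


# -- payload serialization ----------------------------------------------------


def _texture_of(payload: GeometryPayload) -> EncodedTexture | None:
    t = payload.texture
    if t is None:
        return None
    if isinstance(t, EncodedTexture):
        return t
    if isinstance(t, TextureImage):
        data, tag = encode_texture(t)
        return EncodedTexture(data, tag)
    raise ValidationError(f"unsupported texture object: {type(t).__name__}")


def _write_payload(buf: io.BytesIO, payload: GeometryPayload, manifest: Manifest) -> None:
    if payload.kind not in _KINDS:
        raise ValidationError(f"unsupported payload kind: {payload.kind!r}")
    _w_u32(buf, _KINDS.index(payload.kind))
    buf.write(struct.pack("<4f", *payload.colour, payload.opacity))

    coords = payload.coordinates
    if coords is None:
        _w_u32(buf, 0)
    else:
        shape = coords.shape
        _w_u32(buf, len(shape))
        for d in shape:
            _w_u32(buf, d)
        _w_f32s(buf, coords.reshape(-1))

    if payload.normals is None:
        _w_u32(buf, 0)
    else:
        _w_u32(buf, 1)
        _w_f32s(buf, payload.normals.reshape(-1))

    tex = _texture_of(payload)
    if tex is None:
        _w_u32(buf, 0)
    else:
        _w_u32(buf, 1)
        _w_str(buf, tex.tag)
        _w_u32(buf, len(tex.data))
        buf.write(tex.data)
        manifest.texture_digests.append(tex.digest())

    mesh = payload.mesh
    if mesh is None:
        _w_u32(buf, 0)
    else:
        if not isinstance(mesh, IndexedMesh):
            raise ValidationError("payload.mesh must be an IndexedMesh")
        _w_u32(buf, 1)
        _w_f32s(buf, mesh.positions.reshape(-1))
        _w_f32s(buf, mesh.normals.reshape(-1))
        buf.write(struct.pack("<4f", *mesh.colour, mesh.opacity))
        _w_u32(buf, len(mesh.facets))
        for idx in mesh.facets:
            _w_u32(buf, len(idx))
            for i in idx:
                _w_u32(buf, i)


def _read_payload(r: _Reader) -> GeometryPayload:
    kind_idx = r.u32()
    if kind_idx >= len(_KINDS):
        raise ParseError(f"unknown payload kind index {kind_idx}")
    kind = _KINDS[kind_idx]
    cr, cg, cb, op = struct.unpack("<4f", r.take(16))

    ndim = r.u32()
    coords = None
    if ndim:
        shape = tuple(r.u32() for _ in range(ndim))
        coords = r.f32s().reshape(shape)

    normals = None
    if r.u32():
        flat = r.f32s()
        normals = flat.reshape(-1, 3)

    texture = None
    if r.u32():
        tag = r.string()
        texture = EncodedTexture(r.take(r.u32()), tag)

    mesh = None
    if r.u32():
        positions = r.f32s().reshape(-1, 3)
        mnormals = r.f32s().reshape(-1, 3)
        mr, mg, mb, mop = struct.unpack("<4f", r.take(16))
        nfac = r.u32()
        facets = []
        for _ in range(nfac):
            arity = r.u32()
            facets.append(tuple(r.u32() for _ in range(arity)))
        mesh = IndexedMesh(positions, mnormals, facets, (mr, mg, mb), mop)

    return GeometryPayload(
        kind=kind,
        coordinates=coords,
        colour=(cr, cg, cb),
        opacity=op,
        texture=texture,
        normals=normals,
        mesh=mesh,
    )


def _write_group(buf: io.BytesIO, group: Group, manifest: Manifest) -> None:
    _w_str(buf, group.short_name)
    _w_str(buf, group.full_name)
    manifest.group_names.append(group.full_name)
    manifest.entity_counts[group.full_name] = len(group.payloads)
    _w_u32(buf, len(group.payloads))
    for p in group.payloads:
        _write_payload(buf, p, manifest)
    _w_u32(buf, len(group.children))
    for child in group.children:
        _write_group(buf, child, manifest)


def _read_group(r: _Reader) -> Group:
    short = r.string()
    full = r.string()
    group = Group(short, full)
    for _ in range(r.u32()):
        group.payloads.append(_read_payload(r))
    for _ in range(r.u32()):
        group.children.append(_read_group(r))
    return group


# -- public API ---------------------------------------------------------------


def write_prc(tree: ModelTree) -> PRCPayload:
    """Serialize a model tree to container bytes plus a manifest."""
    body = io.BytesIO()
    manifest = Manifest()
    _write_group(body, tree.root, manifest)
    compressed = zlib.compress(body.getvalue(), 9)
    data = MAGIC + struct.pack("<I", len(compressed)) + compressed
    return PRCPayload(data, manifest)


def read_prc(data: bytes) -> ModelTree:
    """Reconstruct a model tree from container bytes (round-trip oracle).

    Only streams produced by :func:`write_prc` are supported; foreign 3-d
    containers raise :class:`ParseError`.
    """
    if len(data) < len(MAGIC) + 4 or data[: len(MAGIC)] != MAGIC:
        raise ParseError("not a recognised scene container (bad magic)")
    (clen,) = struct.unpack_from("<I", data, len(MAGIC))
    blob = data[len(MAGIC) + 4 :]
    if len(blob) < clen:
        raise ParseError("scene container truncated")
    try:
        body = zlib.decompress(blob[:clen])
    except zlib.error as exc:
        raise ParseError(f"scene container corrupt: {exc}") from exc
    r = _Reader(body)
    root = _read_group(r)
    if r.pos != len(body):
        raise ParseError("trailing bytes after scene tree")

    tree = ModelTree.__new__(ModelTree)
    tree._serials = {}
    tree.root = root
    tree._current = root
    # restore serial counters so further register_group calls stay unique
    for g in tree.groups():
        short, full = g.short_name, g.full_name
        if full.startswith(short) and full[len(short) :].isdigit():
            serial = int(full[len(short) :])
            tree._serials[short] = max(tree._serials.get(short, 0), serial)
    return tree


# -- structural equality (test oracle) ----------------------------------------


def _textures_equal(a, b) -> bool:
    ea = a if isinstance(a, EncodedTexture) else (None if a is None else EncodedTexture(*encode_texture(a)))
    eb = b if isinstance(b, EncodedTexture) else (None if b is None else EncodedTexture(*encode_texture(b)))
    if (ea is None) != (eb is None):
        return False
    return ea is None or (ea.tag == eb.tag and ea.data == eb.data)


def _payloads_equal(a: GeometryPayload, b: GeometryPayload, tol: float) -> bool:
    if a.kind != b.kind:
        return False
    if not np.allclose(a.colour, b.colour, atol=tol) or abs(a.opacity - b.opacity) > tol:
        return False
    for xa, xb in ((a.coordinates, b.coordinates), (a.normals, b.normals)):
        if (xa is None) != (xb is None):
            return False
        if xa is not None and (xa.shape != xb.shape or not np.allclose(xa, xb, atol=tol)):
            return False
    if not _textures_equal(a.texture, b.texture):
        return False
    ma, mb = a.mesh, b.mesh
    if (ma is None) != (mb is None):
        return False
    if ma is not None:
        if ma.facets != mb.facets:
            return False
        if not np.allclose(ma.positions, mb.positions, atol=tol):
            return False
        if not np.allclose(ma.normals, mb.normals, atol=tol, equal_nan=True):
            return False
        if not np.allclose(ma.colour, mb.colour, atol=tol) or abs(ma.opacity - mb.opacity) > tol:
            return False
    return True


def structural_equal(a: ModelTree, b: ModelTree, tol: float = 1e-6) -> bool:
    """Structural scene equality at float32 fidelity (names/counts exact)."""

    def groups_equal(ga: Group, gb: Group) -> bool:
        if ga.short_name != gb.short_name or ga.full_name != gb.full_name:
            return False
        if len(ga.payloads) != len(gb.payloads) or len(ga.children) != len(gb.children):
            return False
        return all(
            _payloads_equal(pa, pb, tol) for pa, pb in zip(ga.payloads, gb.payloads)
        ) and all(groups_equal(ca, cb) for ca, cb in zip(ga.children, gb.children))

    return groups_equal(a.root, b.root)
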