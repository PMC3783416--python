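"""Surface mesh compression: facet soups -> per-colour vertex-indexed meshes.

A facet soup stores every vertex of every facet independently.  In a typical
surface mesh each vertex is shared by three or four facets, so welding
vertices into a single (position, normal) record list indexed by the facets
saves considerable space, and indexed meshes also load and render much faster
in PDF viewers.  Colours are stored once per mesh rather than per facet:
multi-coloured surfaces are first quantized by a greedy pass that merges each
facet into the first existing mesh whose representative colour lies within a
threshold distance in RGB space, starting a new mesh otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError
from .mesh_io import Facet, FacetSoup

#: Default RGB-space grouping distance for colour quantization.  The euclidean
#: metric on the unit RGB cube is used.  This default is this package's
#: choice, not a published value.
DEFAULT_COLOUR_THRESHOLD = 0.05


@dataclass
class IndexedMesh:
    """Single-colour mesh: welded (position, normal) records + index lists.

    ``normals`` rows may contain NaN where the source facet had no normal;
    NaN-normals form their own dedupe class.
    """

    positions: np.ndarray  # (nrec, 3)
    normals: np.ndarray  # (nrec, 3), NaN rows = "no normal"
    facets: list[tuple[int, ...]]  # 3- or 4-index tuples
    colour: tuple[float, float, float]
    opacity: float = 1.0

    @property
    def n_records(self) -> int:
        return len(self.positions)

    def expand(self) -> FacetSoup:
        """Expand back to an unshared facet soup (inverse of welding)."""
        facets = []
        for idx in self.facets:
            nrm = self.normals[idx[0]]
            facets.append(
                Facet(
                    self.positions[list(idx)],
                    None if np.any(np.isnan(nrm)) else nrm,
                    self.colour,
                    self.opacity,
                )
            )
        return FacetSoup(facets)


@dataclass
class CompressionStats:
    """Per-run bookkeeping exposed for logging."""

    facets_in: int = 0
    meshes_out: int = 0
    records_before: int = 0
    records_after: int = 0

    @property
    def savings(self) -> float:
        if self.records_before == 0:
            return 0.0
        return 1.0 - self.records_after / self.records_before


def _dedupe_key(pos: np.ndarray, nrm: Optional[np.ndarray], tol: float):
    if tol == 0.0:
        pk = tuple(pos.tolist())
        nk = None if nrm is None else tuple(nrm.tolist())
    else:
        pk = tuple(np.round(pos / tol).astype(np.int64).tolist())
        nk = None if nrm is None else tuple(np.round(nrm / tol).astype(np.int64).tolist())
    return pk, nk


def build_indexed_mesh(
    facets: FacetSoup | list[Facet],
    position_tolerance: float = 0.0,
) -> IndexedMesh:
    """Weld the vertices of a single-colour facet collection into an indexed mesh.

    Vertex records are deduplicated on the pair (position, facet normal):
    exactly (bitwise) when *position_tolerance* is 0, else by snapping both to
    a grid of that pitch.  Facets sharing a vertex but disagreeing on the
    normal therefore keep separate records, preserving shading seams.  All
    facets must share one (colour, opacity); a mixed collection is a contract
    violation.
    """
    flist = list(facets)
    if not flist:
        raise ValidationError("cannot index an empty facet collection")
    if position_tolerance < 0:
        raise ValidationError("position tolerance must be >= 0")
    colour, opacity = flist[0].colour, flist[0].opacity
    for f in flist:
        if f.colour != colour or f.opacity != opacity:
            raise ValidationError("all facets in one mesh must share colour and opacity")

    records: dict[tuple, int] = {}
    positions: list[np.ndarray] = []
    normals: list[np.ndarray] = []
    index_lists: list[tuple[int, ...]] = []
    for f in flist:
        idx = []
        for v in f.vertices:
            key = _dedupe_key(v, f.normal, position_tolerance)
            rec = records.get(key)
            if rec is None:
                rec = len(positions)
                records[key] = rec
                positions.append(v)
                normals.append(f.normal if f.normal is not None else np.full(3, np.nan))
            idx.append(rec)
        index_lists.append(tuple(idx))
    return IndexedMesh(
        np.asarray(positions, dtype=np.float64).reshape(len(positions), 3),
        np.asarray(normals, dtype=np.float64).reshape(len(normals), 3),
        index_lists,
        colour,
        opacity,
    )


def group_facets_by_colour(
    soup: FacetSoup,
    rgb_threshold: float = DEFAULT_COLOUR_THRESHOLD,
    position_tolerance: float = 0.0,
    stats: Optional[CompressionStats] = None,
) -> list[IndexedMesh]:
    """Quantize facet colours and build one indexed mesh per colour class.

    Greedy sequential pass in input order: each facet joins the first
    existing class whose representative colour (the colour of the facet that
    founded the class) is within *rgb_threshold* euclidean distance in the
    RGB unit cube — opacity must also match exactly — else it founds a new
    class.  With threshold 0 this reduces to exact-colour partitioning.
    """
    if rgb_threshold < 0:
        raise ValidationError("rgb threshold must be >= 0")
    classes: list[tuple[np.ndarray, float, list[Facet]]] = []
    for f in soup:
        c = np.asarray(f.colour)
        for rep, rep_op, members in classes:
            if rep_op == f.opacity and float(np.linalg.norm(c - rep)) <= rgb_threshold:
                members.append(f)
                break
        else:
            classes.append((c, f.opacity, [f]))

    meshes = []
    for rep, rep_op, members in classes:
        # the representative colour (first facet's) is the mesh colour
        recoloured = [
            Facet(f.vertices, f.normal, tuple(rep.tolist()), rep_op) for f in members
        ]
        meshes.append(build_indexed_mesh(recoloured, position_tolerance))

    if stats is not None:
        stats.facets_in += len(soup)
        stats.meshes_out += len(meshes)
        stats.records_before += sum(len(f.vertices) for f in soup)
        stats.records_after += sum(m.n_records for m in meshes)
    return meshes
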