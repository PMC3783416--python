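"""Vertex welding and colour-quantized mesh grouping, against brute-force oracles."""

import numpy as np
import pytest

from fig3d.errors import ValidationError
from fig3d.mesh_compress import (
    CompressionStats,
    build_indexed_mesh,
    group_facets_by_colour,
)
from fig3d.mesh_io import Facet, FacetSoup


def tri(verts, normal=None, colour=(0.5, 0.5, 0.5), opacity=1.0):
    return Facet(np.asarray(verts, dtype=float), normal, colour, opacity)


def brute_force_record_count(facets, tol=0.0):
    """O(n^2) dedupe oracle over (position, normal) pairs."""
    records = []
    for f in facets:
        for v in f.vertices:
            n = f.normal
            dup = False
            for rv, rn in records:
                if not np.array_equal(v, rv):
                    continue
                if (n is None) != (rn is None):
                    continue
                if n is not None and not np.array_equal(n, rn):
                    continue
                dup = True
                break
            if not dup:
                records.append((v.copy(), None if n is None else n.copy()))
    return len(records)


class TestBuildIndexedMesh:
    SHARED = [
        [[0, 0, 0], [1, 0, 0], [0, 1, 0]],
        [[1, 0, 0], [1, 1, 0], [0, 1, 0]],
    ]

    def test_shared_edge_same_normal_welds_to_four_records(self):
        n = np.array([0.0, 0.0, 1.0])
        mesh = build_indexed_mesh([tri(v, n) for v in self.SHARED])
        assert mesh.n_records == 4
        assert len(mesh.facets) == 2

    def test_differing_normals_keep_records_apart(self):
        mesh = build_indexed_mesh(
            [
                tri(self.SHARED[0], np.array([0.0, 0.0, 1.0])),
                tri(self.SHARED[1], np.array([0.0, 1.0, 0.0])),
            ]
        )
        assert mesh.n_records == 6

    def test_mixed_colours_rejected(self):
        with pytest.raises(ValidationError, match="colour"):
            build_indexed_mesh(
                [tri(self.SHARED[0], colour=(1, 0, 0)), tri(self.SHARED[1])]
            )

    def test_random_facets_match_quadratic_oracle(self, rng):
        # some facets share vertices, some have normals
        base = rng.integers(0, 4, (50, 3, 3)).astype(float)
        normals = [
            np.array([0.0, 0.0, 1.0]) if rng.random() < 0.5 else None
            for _ in range(50)
        ]
        facets = [tri(v, n) for v, n in zip(base, normals)]
        mesh = build_indexed_mesh(facets)
        assert mesh.n_records == brute_force_record_count(facets)
        # expansion reproduces the input facets in order
        expanded = mesh.expand()
        assert len(expanded) == 50
        for a, b in zip(facets, expanded):
            assert np.array_equal(a.vertices, b.vertices)

    def test_every_index_in_bounds(self, random_soup):
        mesh = build_indexed_mesh(random_soup.facets)
        assert all(max(idx) < mesh.n_records for idx in mesh.facets)


def greedy_oracle(colours, opacities, threshold):
    """Independent re-simulation of the grouping pass."""
    classes = []
    assignment = []
    for c, op in zip(colours, opacities):
        for ci, (rep, rop) in enumerate(classes):
            if rop == op and np.linalg.norm(np.asarray(c) - rep) <= threshold:
                assignment.append(ci)
                break
        else:
            classes.append((np.asarray(c, dtype=float), op))
            assignment.append(len(classes) - 1)
    return classes, assignment


class TestGroupByColour:
    def test_uniform_colour_threshold_zero_is_one_mesh(self, random_soup):
        assert len(group_facets_by_colour(random_soup, 0.0)) == 1

    def test_distant_colours_stay_apart(self):
        soup = FacetSoup(
            [
                tri([[0, 0, 0], [1, 0, 0], [0, 1, 0]], colour=(1, 0, 0)),
                tri([[0, 0, 0], [1, 0, 0], [0, 1, 0]], colour=(0, 0, 1)),
            ]
        )
        assert len(group_facets_by_colour(soup, 0.1)) == 2

    def test_negative_threshold_rejected(self, random_soup):
        with pytest.raises(ValidationError):
            group_facets_by_colour(random_soup, -0.1)

    def test_thousand_random_colours_match_greedy_oracle(self, rng):
        colours = rng.random((1000, 3))
        verts = rng.uniform(-1, 1, (1000, 3, 3))
        soup = FacetSoup(
            [tri(v, colour=tuple(c)) for v, c in zip(verts, colours)]
        )
        meshes = group_facets_by_colour(soup, 0.2)
        classes, assignment = greedy_oracle(colours, [1.0] * 1000, 0.2)
        assert len(meshes) == len(classes)
        # mesh k's facet count equals the oracle class size
        from collections import Counter

        sizes = Counter(assignment)
        for k, m in enumerate(meshes):
            assert len(m.facets) == sizes[k]
            assert np.allclose(m.colour, classes[k][0])
        # every facet within threshold of its mesh colour
        for k, ci in enumerate(assignment):
            assert np.linalg.norm(colours[k] - np.asarray(meshes[ci].colour)) <= 0.2

    def test_facet_conservation_and_vertex_subset(self, rng):
        colours = rng.random((100, 3))
        verts = rng.uniform(-1, 1, (100, 3, 3))
        soup = FacetSoup([tri(v, colour=tuple(c)) for v, c in zip(verts, colours)])
        meshes = group_facets_by_colour(soup, 0.3)
        assert sum(len(m.facets) for m in meshes) == len(soup)
        inputs = {tuple(v) for f in soup for v in f.vertices}
        for m in meshes:
            for p in m.positions:
                assert tuple(p) in inputs

    def test_mesh_count_monotone_in_threshold(self, rng):
        colours = rng.random((200, 3))
        verts = rng.uniform(-1, 1, (200, 3, 3))
        soup = FacetSoup([tri(v, colour=tuple(c)) for v, c in zip(verts, colours)])
        counts = [
            len(group_facets_by_colour(soup, th))
            for th in (0.0, 0.05, 0.1, 0.2, 0.4, 0.8, 2.0)
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 1  # threshold 2 > sqrt(3) merges everything

    def test_threshold_zero_is_exact_colour_partition(self, rng):
        palette = [(1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)]
        soup = FacetSoup(
            [
                tri(rng.uniform(-1, 1, (3, 3)), colour=palette[i % 3])
                for i in range(30)
            ]
        )
        meshes = group_facets_by_colour(soup, 0.0)
        assert len(meshes) == 3

    def test_stats_accumulate(self, random_soup):
        stats = CompressionStats()
        group_facets_by_colour(random_soup, 0.05, stats=stats)
        assert stats.facets_in == 50
        assert stats.records_before == 150
        assert 0 < stats.records_after <= 150
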