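"""Surface format readers: STL, OBJ, FreeSurfer ASCII surface/weights."""

import numpy as np
import pytest

from fig3d.errors import ParseError
from fig3d.mesh_io import (
    FacetSoup,
    read_fs_surface,
    read_fs_weights,
    read_obj,
    read_stl,
    write_fs_surface,
    write_fs_weights,
    write_obj,
    write_stl_binary,
)
from fig3d.synth import FixtureSpec, synth_mesh

ASCII_STL = """solid test
  facet normal 0 0 1
    outer loop
      vertex 0 0 0
      vertex 1 0 0
      vertex 0 1 0
    endloop
  endfacet
endsolid test
"""


class TestSTL:
    def test_ascii_single_facet(self):
        soup = read_stl(ASCII_STL)
        assert len(soup) == 1
        f = soup.facets[0]
        assert np.allclose(f.normal, [0, 0, 1])
        assert np.allclose(f.vertices, [[0, 0, 0], [1, 0, 0], [0, 1, 0]])

    def test_binary_roundtrip_counts(self, random_soup):
        data = write_stl_binary(random_soup)
        back = read_stl(data)
        assert len(back) == len(random_soup)
        for a, b in zip(random_soup, back):
            assert np.allclose(a.vertices, b.vertices, atol=1e-6)

    def test_binary_truncated_count_rejected(self, random_soup):
        data = bytearray(write_stl_binary(random_soup))
        import struct

        struct.pack_into("<I", data, 80, len(random_soup) + 3)
        with pytest.raises(ParseError, match="truncated"):
            read_stl(bytes(data))

    def test_colour_and_opacity_applied(self):
        soup = read_stl(ASCII_STL, colour=(1, 0, 0), opacity=0.5)
        assert soup.facets[0].colour == (1.0, 0.0, 0.0)
        assert soup.facets[0].opacity == 0.5


class TestOBJ:
    def test_positive_indices(self):
        soup = read_obj("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 3\n")
        assert len(soup) == 1
        assert np.allclose(soup.facets[0].vertices, [[0, 0, 0], [1, 0, 0], [0, 1, 0]])

    def test_negative_indices_identical_triangle(self):
        pos = read_obj("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 3\n")
        neg = read_obj("v 0 0 0\nv 1 0 0\nv 0 1 0\nf -3 -2 -1\n")
        assert np.allclose(pos.facets[0].vertices, neg.facets[0].vertices)

    def test_quads_preserved(self):
        soup = read_obj("v 0 0 0\nv 1 0 0\nv 1 1 0\nv 0 1 0\nf 1 2 3 4\n")
        assert len(soup) == 1
        assert soup.facets[0].vertices.shape == (4, 3)

    def test_pentagon_fan_triangulated(self):
        text = "\n".join(
            f"v {np.cos(a):.6f} {np.sin(a):.6f} 0"
            for a in np.linspace(0, 2 * np.pi, 6)[:5]
        )
        soup = read_obj(text + "\nf 1 2 3 4 5\n")
        assert len(soup) == 3
        assert all(f.vertices.shape == (3, 3) for f in soup)

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ParseError, match="out of range"):
            read_obj("v 0 0 0\nf 1 2 3\n")

    def test_writer_reader_roundtrip(self, random_soup):
        back = read_obj(write_obj(random_soup))
        assert len(back) == len(random_soup)
        a = np.sort(np.concatenate([f.vertices for f in random_soup]), axis=0)
        b = np.sort(np.concatenate([f.vertices for f in back]), axis=0)
        assert np.allclose(a, b, atol=1e-6)


class TestFreeSurferSurface:
    MINIMAL = "#!ascii\n3 1\n0 0 0 0\n1 0 0 0\n0 1 0 0\n0 1 2 0\n"

    def test_minimal_file(self):
        soup, verts, faces = read_fs_surface(self.MINIMAL)
        assert len(soup) == 1
        assert verts.shape == (3, 3)
        assert faces.tolist() == [[0, 1, 2]]

    def test_out_of_bound_face_index_rejected(self):
        bad = self.MINIMAL.replace("0 1 2 0", "0 1 3 0")
        with pytest.raises(ParseError, match="out of range"):
            read_fs_surface(bad)

    def test_count_mismatch_rejected(self):
        with pytest.raises(ParseError):
            read_fs_surface("#!ascii\n3 2\n0 0 0 0\n1 0 0 0\n0 1 0 0\n0 1 2 0\n")

    def test_sphere_roundtrip_preserves_counts(self):
        # generator comparison: weld the synthetic sphere into a vertex/face
        # table, write it, read it back
        soup = synth_mesh(FixtureSpec("uv_sphere_mesh", segments=8))["sphere"]
        seen: dict[tuple, int] = {}
        faces = []
        for f in soup:
            idx = []
            for v in f.vertices:
                key = tuple(v.tolist())
                idx.append(seen.setdefault(key, len(seen)))
            faces.append(idx)
        verts = np.array(list(seen.keys()))
        text = write_fs_surface(verts, np.array(faces))
        back_soup, back_verts, back_faces = read_fs_surface(text)
        assert back_verts.shape == verts.shape
        assert back_faces.shape == (len(faces), 3)
        assert len(back_soup) == len(soup)


class TestFreeSurferWeights:
    def test_sparse_pairs(self):
        w = read_fs_weights("0\n2\n5 0.5\n9 1.0\n")
        assert w.weights == {5: 0.5, 9: 1.0}
        assert w[0] == 0.0  # unlisted vertices weigh zero

    def test_zero_count_is_empty(self):
        assert len(read_fs_weights("0\n0\n")) == 0

    def test_index_beyond_bound_rejected(self):
        with pytest.raises(ParseError, match="bound"):
            read_fs_weights("0\n1\n9 1.0\n", vertex_bound=8)

    def test_count_mismatch_rejected(self):
        with pytest.raises(ParseError):
            read_fs_weights("0\n3\n5 0.5\n")

    def test_writer_reader_roundtrip(self):
        from fig3d.mesh_io import VertexWeights

        w = VertexWeights({0: 1.5, 7: -2.0, 3: 0.25})
        assert read_fs_weights(write_fs_weights(w)).weights == w.weights
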