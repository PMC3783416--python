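"""Scene container round trip and PDF structural probes.

The PDF checks use the standalone parser in ``fig3d.pdfcheck``, which shares
no code with the writer.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fig3d.errors import ParseError, ValidationError
from fig3d.mesh_compress import build_indexed_mesh
from fig3d.mesh_io import Facet
from fig3d.pdfcheck import PDFDocument
from fig3d.pdfwriter import Figure3D, embed_pdf
from fig3d.prc import read_prc, structural_equal, write_prc
from fig3d.scene import GeometryPayload, ModelTree
from fig3d.texture import TextureImage
from fig3d.views import default_presets


def make_scene(seed: int) -> ModelTree:
    """Deterministic random scene covering every payload kind."""
    rng = np.random.default_rng(seed)
    t = ModelTree()
    t.add_payload(GeometryPayload("points", rng.uniform(-1, 1, (5, 3))))
    for name in ["skull", "muscle", "skull"][: int(rng.integers(1, 4))]:
        t.register_group(name)
        kind = rng.integers(0, 4)
        if kind == 0:
            t.add_payload(GeometryPayload("lines", rng.uniform(-1, 1, (3, 2, 3))))
        elif kind == 1:
            t.add_payload(
                GeometryPayload(
                    "facets",
                    rng.uniform(-1, 1, (2, 3, 3)),
                    colour=tuple(rng.random(3)),
                    opacity=float(rng.random()),
                )
            )
        elif kind == 2:
            facets = [
                Facet(rng.uniform(-1, 1, (3, 3)), None, (0.2, 0.4, 0.6))
                for _ in range(4)
            ]
            t.add_payload(
                GeometryPayload("indexed_mesh", mesh=build_indexed_mesh(facets))
            )
        else:
            tex = TextureImage(rng.integers(0, 256, (8, 8, 4), dtype=np.uint8))
            t.add_payload(
                GeometryPayload(
                    "billboard",
                    np.array([[-1, -1, 0], [1, -1, 0], [1, 1, 0], [-1, 1, 0]], float),
                    texture=tex,
                )
            )
    return t


class TestPRCRoundTrip:
    def test_empty_tree_manifest_lists_root_only(self):
        payload = write_prc(ModelTree())
        assert payload.manifest.group_names == ["S2ROOT1"]
        assert payload.manifest.entity_counts == {"S2ROOT1": 0}

    def test_manifest_counts_entities(self):
        t = ModelTree()
        t.register_group("cortex")
        facets = [Facet(np.eye(3), None, (1, 0, 0))]
        t.add_payload(GeometryPayload("indexed_mesh", mesh=build_indexed_mesh(facets)))
        payload = write_prc(t)
        assert payload.manifest.entity_counts["cortex1"] == 1
        assert "cortex1" in payload.manifest.group_names

    @pytest.mark.parametrize("seed", range(8))
    def test_fuzzed_scenes_roundtrip_structurally(self, seed):
        t = make_scene(seed)
        back = read_prc(write_prc(t).bytes)
        assert structural_equal(t, back)

    def test_textured_billboard_digest_preserved(self):
        t = make_scene(3)
        payload = write_prc(t)
        back = read_prc(payload.bytes)
        again = write_prc(back)
        assert payload.manifest.texture_digests == again.manifest.texture_digests
        assert payload.bytes == again.bytes

    def test_group_order_preserved(self):
        t = ModelTree()
        order = [t.register_group(n) for n in ["b", "a", "c", "a"]]
        back = read_prc(write_prc(t).bytes)
        assert [g.full_name for g in back.root.children] == order

    def test_truncated_payload_rejected(self):
        data = write_prc(make_scene(0)).bytes
        with pytest.raises(ParseError):
            read_prc(data[: len(data) // 2])

    def test_foreign_bytes_rejected(self):
        with pytest.raises(ParseError, match="magic"):
            read_prc(b"not a scene container at all")

    def test_determinism_byte_identical(self):
        a = write_prc(make_scene(5)).bytes
        b = write_prc(make_scene(5)).bytes
        assert a == b

    def test_register_after_roundtrip_stays_unique(self):
        t = ModelTree()
        t.register_group("net")
        back = read_prc(write_prc(t).bytes)
        assert back.register_group("net") == "net2"


def poster(w=32, h=24):
    px = np.zeros((h, w, 4), dtype=np.uint8)
    px[:, :, 0] = np.linspace(0, 255, w, dtype=np.uint8)
    px[:, :, 3] = 255
    return TextureImage(px)


def make_figure(seed=1, presets=None, activation="click"):
    return Figure3D(
        prc=write_prc(make_scene(seed)),
        poster=poster(),
        presets=default_presets() if presets is None else presets,
        script="// controls\n",
        activation=activation,
    )


class TestEmbedPDF:
    def test_single_3d_annotation_with_byte_equal_stream(self):
        fig = make_figure()
        doc = PDFDocument(embed_pdf(fig))
        annots = doc.annotations_of_subtype("3D")
        assert len(annots) == 1
        assert doc.stream_bytes(annots[0]["3DD"]) == fig.prc.bytes

    def test_poster_appearance_present(self):
        doc = PDFDocument(embed_pdf(make_figure()))
        [annot] = doc.annotations_of_subtype("3D")
        ap = doc.resolve(annot["AP"])
        form = doc.stream_dict(ap["N"])
        assert form["Subtype"] == "Form"
        # the form draws an image XObject (the poster)
        img_ref = doc.resolve(form["Resources"])["XObject"]["Poster"]
        img = doc.stream_dict(img_ref)
        assert img["Subtype"] == "Image"
        assert img["Width"] == 32 and img["Height"] == 24

    def test_view_count_matches_presets(self):
        fig = make_figure()
        doc = PDFDocument(embed_pdf(fig))
        [annot] = doc.annotations_of_subtype("3D")
        stream_dict = doc.stream_dict(annot["3DD"])
        views = [doc.resolve(r) for r in stream_dict["VA"]]
        assert len(views) == len(fig.presets) == 7
        assert [v["XN"].decode() for v in views] == [p.name for p in fig.presets]
        # first preset is the default view
        assert doc.resolve(stream_dict["DV"])["XN"].decode() == fig.presets[0].name

    def test_part_visibility_reaches_view_dict(self):
        from fig3d.views import PartOverride, ViewPreset

        preset = ViewPreset(
            "One net", (0, 1, 0), parts=[PartOverride("net2", False)]
        )
        doc = PDFDocument(embed_pdf(make_figure(presets=[preset])))
        [annot] = doc.annotations_of_subtype("3D")
        [view] = [doc.resolve(r) for r in doc.stream_dict(annot["3DD"])["VA"]]
        [node] = view["NA"]
        assert node["N"].decode() == "net2"
        assert node["V"] is False

    @pytest.mark.parametrize("activation,flag", [("auto", "PO"), ("click", "XA")])
    def test_activation_flag(self, activation, flag):
        doc = PDFDocument(embed_pdf(make_figure(activation=activation)))
        [annot] = doc.annotations_of_subtype("3D")
        assert doc.resolve(annot["3DA"])["A"] == flag

    def test_script_attached_on_instantiate(self):
        fig = make_figure()
        doc = PDFDocument(embed_pdf(fig))
        [annot] = doc.annotations_of_subtype("3D")
        ref = doc.stream_dict(annot["3DD"])["OnInstantiate"]
        assert doc.stream_bytes(ref) == fig.script.encode()

    def test_determinism_byte_identical_pdf(self):
        assert embed_pdf(make_figure()) == embed_pdf(make_figure())

    def test_bad_activation_rejected(self):
        with pytest.raises(ValidationError):
            Figure3D(write_prc(ModelTree()), poster(), activation="hover")

    def test_duplicate_preset_names_rejected(self):
        presets = [default_presets()[0], default_presets()[0]]
        with pytest.raises(ValidationError, match="unique"):
            make_figure(presets=presets)
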