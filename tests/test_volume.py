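"""XRW container, stacking, transfer functions, slice sets, equalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fig3d.errors import ParseError, ValidationError
from fig3d.texture import TextureImage
from fig3d.volume import (
    INTENSITY_MAX,
    SliceSet,
    TransferFunction,
    Volume,
    apply_transfer,
    build_slice_sets,
    composite_slices,
    default_opacity_factors,
    read_xrw,
    rescale_opacity,
    select_slice_set,
    stack_to_volume,
    write_xrw,
)

dims_st = st.tuples(
    st.integers(1, 6), st.integers(1, 6), st.integers(1, 6)
)


class TestXRW:
    def test_small_roundtrip_bit_exact(self, rng):
        v = Volume(rng.integers(0, 65536, (4, 4, 4), dtype=np.uint16), (1.0, 2.0, 0.5))
        back = read_xrw(write_xrw(v))
        assert back.samples.tobytes() == v.samples.tobytes()
        assert back.dims == v.dims
        assert back.spacing == pytest.approx(v.spacing)

    @given(dims=dims_st, seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_fuzzed_roundtrip_bit_exact(self, dims, seed):
        rng = np.random.default_rng(seed)
        nz, ny, nx = dims
        v = Volume(rng.integers(0, 65536, (nz, ny, nx), dtype=np.uint16))
        back = read_xrw(write_xrw(v))
        assert np.array_equal(back.samples, v.samples)
        assert back.dims == v.dims

    def test_bad_magic_rejected(self, rng):
        data = bytearray(write_xrw(Volume(np.zeros((2, 2, 2), dtype=np.uint16))))
        data[:4] = b"JUNK"
        with pytest.raises(ParseError, match="magic"):
            read_xrw(bytes(data))

    def test_zero_dim_header_rejected(self):
        import struct

        data = b"XRW2" + struct.pack("<3I3f", 0, 4, 4, 1, 1, 1)
        with pytest.raises(ParseError, match="dims"):
            read_xrw(data)

    def test_truncated_payload_rejected(self):
        data = write_xrw(Volume(np.zeros((4, 4, 4), dtype=np.uint16)))
        with pytest.raises(ParseError, match="truncated"):
            read_xrw(data[:-10])


class TestStackToVolume:
    def test_normalisation_to_full_scale(self, rng):
        slices = [rng.integers(0, 256, (16, 16)).astype(np.uint8) for _ in range(8)]
        v = stack_to_volume(slices)
        assert v.dims == (16, 16, 8)
        assert int(v.samples.max()) == INTENSITY_MAX
        assert int(v.samples.min()) == 0

    def test_mixed_dimensions_rejected(self):
        with pytest.raises(ValidationError):
            stack_to_volume([np.zeros((16, 16)), np.zeros((16, 17))])

    def test_single_slice_gives_depth_one(self):
        v = stack_to_volume([np.arange(12.0).reshape(3, 4)])
        assert v.dims == (4, 3, 1)

    def test_constant_stack_maps_to_zero(self):
        v = stack_to_volume([np.full((4, 4), 7.0)] * 3)
        assert int(v.samples.max()) == 0


class TestTransferFunction:
    def test_floor_and_ceiling(self):
        tf = TransferFunction("greyscale", (0.0, float(INTENSITY_MAX)), 1.0)
        v = Volume(np.array([[[0, INTENSITY_MAX]]], dtype=np.uint16))
        rgba = apply_transfer(v, tf)
        assert np.allclose(rgba[0, 0, 0], [0, 0, 0, 0])
        assert np.allclose(rgba[0, 0, 1], [1, 1, 1, 1])

    def test_alpha_nondecreasing_over_all_intensities(self):
        tf = TransferFunction("hotiron", (10000.0, 50000.0), 0.8)
        alphas = tf.alphas(np.arange(65536))
        assert np.all(np.diff(alphas) >= 0)
        assert alphas[0] == 0.0
        assert alphas[-1] == pytest.approx(0.8)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValidationError):
            TransferFunction(window=(100.0, 100.0))

    def test_unknown_colourmap_rejected(self):
        with pytest.raises(ValidationError, match="colourmap"):
            TransferFunction("viridis-ish")

    def test_hotiron_breakpoints(self):
        tf = TransferFunction("hotiron")
        cols = tf.colours(np.array([0.0, 1 / 3, 2 / 3, 1.0]))
        assert np.allclose(cols[0], [0, 0, 0])
        assert np.allclose(cols[1], [1, 0, 0])
        assert np.allclose(cols[2], [1, 1, 0])
        assert np.allclose(cols[3], [1, 1, 1])


class TestSliceSets:
    def test_counts_match_dims(self, rng):
        rgba = rng.random((6, 5, 4, 4))  # (nz, ny, nx, 4)
        sx, sy, sz = build_slice_sets(rgba)
        assert (len(sx), len(sy), len(sz)) == (4, 5, 6)
        assert [s.axis for s in (sx, sy, sz)] == ["x", "y", "z"]

    def test_exactly_three_sets(self, rng):
        sets = build_slice_sets(rng.random((2, 3, 4, 4)))
        assert len(sets) == 3

    def test_reassembly_recovers_grid(self, rng):
        rgba = rng.random((3, 4, 5, 4))
        rgba8 = np.round(rgba * 255) / 255.0  # quantize as textures will
        for s in build_slice_sets(rgba8):
            rebuilt = np.zeros_like(rgba8)
            for k, t in enumerate(s.textures):
                px = t.pixels.astype(float) / 255.0
                if s.axis == "x":
                    rebuilt[:, :, k, :] = px.transpose(1, 0, 2)
                elif s.axis == "y":
                    rebuilt[:, k, :, :] = px
                else:
                    rebuilt[k, :, :, :] = px.transpose(1, 0, 2)
            assert np.allclose(rebuilt, rgba8, atol=1 / 255)


def uniform_sets(dims, alpha):
    """Slice sets of a uniform-alpha white volume of the given dims."""
    nx, ny, nz = dims
    rgba = np.empty((nz, ny, nx, 4))
    rgba[..., :3] = 1.0
    rgba[..., 3] = alpha
    return build_slice_sets(rgba)


class TestRescaleOpacity:
    def test_factor_one_is_identity(self):
        sets = uniform_sets((4, 4, 4), 0.3)
        out = rescale_opacity(sets, (1.0, 1.0, 1.0))
        for a, b in zip(sets, out):
            for ta, tb in zip(a.textures, b.textures):
                assert np.array_equal(ta.pixels, tb.pixels)

    def test_full_alpha_stays_full(self):
        sets = uniform_sets((3, 3, 3), 1.0)
        out = rescale_opacity(sets, (0.5, 2.0, 7.0))
        for s in out:
            for t in s.textures:
                assert int(t.pixels[:, :, 3].min()) == 255

    def test_nonpositive_factor_rejected(self):
        sets = uniform_sets((2, 2, 2), 0.5)
        with pytest.raises(ValidationError):
            rescale_opacity(sets, (0.0, 1.0, 1.0))

    def test_default_factors_are_axis_ratios(self):
        assert default_opacity_factors((32, 64, 64)) == (2.0, 1.0, 1.0)

    def test_equalization_within_one_percent(self):
        # anisotropic uniform volume: composited opacity along each axis must
        # agree after default rescaling
        dims = (32, 64, 64)
        sets = rescale_opacity(uniform_sets(dims, 0.05), dims=dims)
        opacities = []
        for s in sets:
            comp = composite_slices(s)
            opacities.append(comp.pixels[:, :, 3].astype(float).mean() / 255.0)
        assert max(opacities) - min(opacities) < 0.01
        # and without rescaling they would disagree grossly
        raw = [
            composite_slices(s).pixels[:, :, 3].astype(float).mean() / 255.0
            for s in uniform_sets(dims, 0.05)
        ]
        assert max(raw) - min(raw) > 0.1


class TestSelectSliceSet:
    @pytest.mark.parametrize(
        "direction,axis",
        [
            ((1, 0, 0), "x"),
            ((0, 0, 1), "z"),
            ((0, -1, 0.2), "y"),
            ((1, 1, 0), "x"),  # tie-break x < y
            ((0, 1, 1), "y"),  # tie-break y < z
        ],
    )
    def test_dominant_axis(self, direction, axis):
        assert select_slice_set(direction) == axis

    def test_negation_invariance(self, rng):
        for _ in range(50):
            d = rng.standard_normal(3)
            if np.linalg.norm(d) < 1e-6:
                continue
            assert select_slice_set(d) == select_slice_set(-d)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValidationError):
            select_slice_set((0, 0, 0))


class TestComposite:
    def test_single_opaque_slice_is_identity(self, rng):
        px = rng.integers(0, 256, (4, 4, 4), dtype=np.uint8)
        px[:, :, 3] = 255
        s = SliceSet("z", [TextureImage(px)])
        assert np.array_equal(composite_slices(s).pixels, px)

    def test_half_white_over_black(self):
        black = np.zeros((2, 2, 4), dtype=np.uint8)
        black[:, :, 3] = 255
        white = np.full((2, 2, 4), 255, dtype=np.uint8)
        white[:, :, 3] = 128  # ~0.5
        s = SliceSet("z", [TextureImage(black), TextureImage(white)])
        out = composite_slices(s).pixels
        assert np.all(np.abs(out[:, :, :3].astype(int) - 128) <= 1)
        assert np.all(out[:, :, 3] == 255)

    @pytest.mark.parametrize("n,alpha", [(1, 0.3), (5, 0.1), (20, 0.05), (64, 0.02)])
    def test_accumulation_matches_closed_form(self, n, alpha):
        sets = uniform_sets((2, 2, n), alpha)
        out = composite_slices(sets[2])
        expected = 1 - (1 - round(alpha * 255) / 255) ** n
        got = out.pixels[:, :, 3].astype(float).mean() / 255.0
        assert got == pytest.approx(expected, abs=2 / 255 + n / 510)
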