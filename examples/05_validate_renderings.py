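"""Comparing two renderings: difference image and edge overlay.

Composites the same synthetic volume under two slightly different transfer
functions and quantifies the disagreement the way screenshot comparisons
are made: a smoothed greyscale difference image (for volume renders) and a
coloured edge overlay (for surface renders).
"""

from fig3d import (
    FixtureSpec,
    TransferFunction,
    apply_transfer,
    build_slice_sets,
    composite_slices,
    difference_image,
    edge_overlay,
    synth_volume,
)

vol = synth_volume(FixtureSpec("gaussian_blob", dims=(32, 32, 32)))


def render(alpha_max):
    tf = TransferFunction("greyscale", (10000.0, 60000.0), alpha_max)
    sets = build_slice_sets(apply_transfer(vol, tf))
    return composite_slices(sets[2])


a = render(0.5)
b = render(0.6)  # slightly more opaque transfer function

rep = difference_image(a, b)
print(f"difference image: mean={rep.mean:.4f} max={rep.max:.4f} (scale 0..1)")
print("a zero mean would be pixel-identical renders; here the opacity change")
print("shows up as a small, spatially smooth residual")

overlay = edge_overlay(a, b)
n_painted = int((overlay.pixels[:, :, :3] != 255).any(axis=2).sum())
print(f"edge overlay: {n_painted} painted pixels; where the two renders'")
print("edges coincide the second colour overdraws the first")
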