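"""Volume rendering a synthetic angiography-like volume into a 3-d PDF.

Builds a spherical-shell test volume (a bright surface inside dark
surroundings, like a vessel wall), maps it through the hotiron transfer
function, equalizes the slice-set opacities, and writes an interactive PDF.
"""

from pathlib import Path

from fig3d import FixtureSpec, TransferFunction, synth_volume
from fig3d.pipeline import PipelineStats, figure_to_pdf, volume_to_figure

out_dir = Path("scratch")
out_dir.mkdir(exist_ok=True)

volume = synth_volume(FixtureSpec("spherical_shell", dims=(24, 32, 32), radius=9))
print(f"volume: {volume.dims[0]}x{volume.dims[1]}x{volume.dims[2]} voxels")

# window out the dark background, cap slice opacity at 0.6
tf = TransferFunction("hotiron", window=(5000.0, 60000.0), alpha_max=0.6)

stats = PipelineStats()
fig = volume_to_figure(volume, tf, stats=stats)
pdf = figure_to_pdf(fig)
(out_dir / "volume.pdf").write_bytes(pdf)

# the three slice sets give one pre-shaded texture per voxel plane per axis;
# a viewer shows whichever set best faces the camera
print(f"slice textures emitted: {stats.slice_textures} (= 24 + 32 + 32)")
print(f"mean texture saving vs raw 32bpp: {sum(stats.texture_savings)/len(stats.texture_savings):.1%}")
print(f"scene payload: {stats.payload_bytes} bytes; PDF: {len(pdf)} bytes")
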