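# fig3d

Interactive, 3-dimensional scientific figures embedded in PDF files.

Journals publish flat projections of inherently 3-d data — MR angiograms,
cortical surfaces with functional activations painted on them, stacked
microscopy sections, segmented anatomical models. PDF's 3-d annotation
extension lets the figure itself be the 3-d scene: readers with a 3-d-capable
viewer can rotate it, select predefined views, and toggle named parts of the
model tree, while every other viewer (and print) falls back to an ordinary
2-d poster image. `fig3d` is a Python library plus a thin command line for
building such figures from surface meshes (STL, OBJ, FreeSurfer ASCII) and
volumetric images (greyscale slice stacks, NIfTI, or the XRW 16-bit volume
container), without any commercial tooling.

## What it does

- **Model tree** — named, hierarchical scene groups; caller-given names get a
  serial suffix (`cortex` → `cortex1`, `cortex2`) guaranteeing uniqueness, and
  the short→full mapping is written to a companion `s2direct.map` file so
  views and scripts can address nodes.
- **Surface mesh compression** — facet soups are welded into vertex-indexed
  meshes: a vertex shared by *k* facets is stored once instead of *k* times,
  and colour is stored once per mesh. Multi-coloured surfaces are first
  quantized by a greedy pass that merges facets whose colours lie within a
  threshold distance *d* of a mesh's representative colour in RGB space.
- **Texture compression** — entirely-opaque textures are stored as JPEG;
  textures with any transparency (volume slices, billboards) become palette
  PNGs with at most 256 distinct RGBA colours, chosen by median-cut and
  applied with Floyd–Steinberg error diffusion. Savings are ≥50 % against
  raw 32-bpp bitmaps on typical smooth textures.
- **Slice-based volume rendering** — a volume is mapped through a transfer
  function (colourmap + opacity ramp) to RGBA voxels and cut into three
  orthogonal *slice sets*, one pre-shaded texture per voxel plane per axis;
  a viewer shows the set whose axis best matches the camera direction.
  Because opacity accumulates as A = 1 − (1 − α)ⁿ along a sight-line through
  n slices, anisotropic volumes are *equalized* by the per-axis rescaling
  α′ = 1 − (1 − α)^f with axis-length ratios as default factors, eliminating
  the visible jump when the active set switches.
- **Views** — seven standard numbered presets (front/back/left/right/top/
  bottom/oblique perspective) plus a text dialect (`s2views.txt`) for custom
  views with per-node VISIBLE overrides.
- **PRC-in-PDF export** — the scene is serialized to a compact deterministic
  binary container and embedded as the 3-d stream of a single-page PDF with
  poster appearance, view dictionaries, activation mode (click or automatic)
  and an attached controls script. An independent structural PDF parser
  (`fig3d.pdfcheck`) verifies emitted files.
- **Rendering validation** — smoothed greyscale difference images and Sobel
  edge overlays for comparing screenshots of the same scene across renderers.

## Worked example

```python
from fig3d import FixtureSpec, TransferFunction, synth_volume
from fig3d.pipeline import PipelineStats, figure_to_pdf, volume_to_figure

volume = synth_volume(FixtureSpec("spherical_shell", dims=(24, 32, 32), radius=9))
tf = TransferFunction("hotiron", window=(5000.0, 60000.0), alpha_max=0.6)
stats = PipelineStats()
fig = volume_to_figure(volume, tf, stats=stats)
open("volume.pdf", "wb").write(figure_to_pdf(fig))
```

This prints (via `stats.log()`):

```
slice textures: 88  encoded bytes: 100664  mean savings vs raw 32bpp: 88.2%
scene payload bytes: 11228
```

88 textures is 24 + 32 + 32 — one per voxel plane per axis, confirming the
three orthogonal slice sets; each is stored ~88 % smaller than a raw 32-bpp
bitmap; the whole interactive scene fits in ~11 kB. The resulting
`volume.pdf` shows the composited poster in any viewer and the rotatable
volume in a 3-d-capable one.

The `examples/` directory holds one short script per capability (volume
rendering, surface meshes, texture compression, model tree + views,
rendering validation); each prints the numbers it computes and what they
mean. The same pipelines are reachable from a shell:

```sh
fig3d stack2xrw slices/ out.xrw
fig3d xrw2pdf out.xrw out.pdf --colourmap hotiron --opacity-scales 2,1,1
fig3d s2stl skull.stl:0.9,0.9,0.8 muscle.stl:0.8,0.2,0.2:0.5 anatomy.pdf
fig3d validate renderA.png renderB.png
```

## Limitations

Only Adobe Acrobat/Reader (desktop) actually renders 3-d PDF content, and no
public reference PRC reader exists, so conformance of the emitted scene
container to external viewers cannot be machine-verified; the automated
contract is the in-repo write→read round trip plus structural PDF probes.
Transparent multi-facet meshes may be drawn in wrong depth order by viewers;
a slow correct work-around (`--unstructured-transparent`) stores them as raw
facet lists instead. See `docs/methods.md` for the full model description,
parameter defaults and design choices.
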