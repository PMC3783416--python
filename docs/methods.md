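# Methods

This note documents the models, algorithms, parameter defaults and design
choices behind `fig3d`, and what the synthetic-data tests do and do not show
about real data.

## Scene model

A figure's geometry lives in a *model tree*: an ordered tree of named groups
whose leaves are geometry payloads (point sets, line sets, independent 3-/4-
vertex facets, vertex-indexed meshes, textured facets, billboards). Viewers
expose this tree to the reader for toggling parts, and views/scripts address
nodes by name, so names must be unique: a group registered under short name
`s` receives the full name `s` + a 1-based decimal serial per short name
(`cortex1`, `cortex2`, …). Payloads added before any group is registered
attach to an implicit root group `S2ROOT1`. The short→full mapping is
serialized to `s2direct.map` as one `short<TAB>full.dotted.path` line per
group, LF-terminated, with `.` separating path components. This dialect is
self-consistent (the parser and all consumers in this package use it) but no
byte-compatibility with other exporters is claimed.

**Billboards** are textured quads that always face the camera. The
orientation transform is the *minimal* rotation (Rodrigues form, no roll)
taking the quad's Newell normal onto the unit vector from the quad centre to
the camera position, applied about the quad centre; centre, edge lengths and
area are invariant. The 180° antiparallel case rotates about an arbitrary
axis perpendicular to the normal. Degenerate cameras (position = target, or
camera at the quad centre) are rejected.

## Mesh compression

Surfaces enter as *facet soups* — independent facets each carrying vertices,
an optional facet normal, an RGB colour and an opacity. Two passes compress
them:

1. **Colour quantization** (`group_facets_by_colour`): a greedy sequential
   pass in input order. Each facet joins the first existing mesh whose
   *representative colour* — the colour of the facet that founded the mesh,
   never an updated mean, keeping the pass order-deterministic — lies within
   a threshold distance in euclidean RGB (unit cube) and whose opacity
   matches exactly; otherwise it founds a new mesh. Threshold 0 degenerates
   to exact-colour partitioning; ties go to the earliest mesh. The default
   threshold 0.05 is this package's choice (no published value exists) —
   small enough that quantization is visually invisible on smooth colourmaps,
   large enough to merge float-rounding colour jitter. The mesh count is
   monotone non-increasing in the threshold for fixed input order (each
   facet's founding condition only relaxes), a property the tests assert.

2. **Vertex welding** (`build_indexed_mesh`): within one single-colour mesh,
   vertex records (position, facet normal) are deduplicated — exactly
   (bitwise) by default, or on a snap grid when a positive position
   tolerance is given — and facets become 3-/4-index lists into the record
   table. Records with differing normals stay separate, preserving shading
   seams. Expansion of the index lists reproduces the input facets in order,
   which is the tested invariant; an O(n²) pairwise dedupe serves as the
   oracle for record counts.

## Texture codec

Classification is strict: a texture is *opaque* iff its minimum alpha is
exactly 1.0 (any pixel below full opacity takes the transparent path).

- Opaque → JPEG (Pillow), default quality 90 — chosen as the standard
  visually-lossless operating point; dimensions are preserved exactly and
  mean per-channel error on smooth gradients stays below 0.05.
- Transparent → palette PNG with ≤ 256 distinct RGBA values. Palette
  selection is median-cut over RGBA with alpha weighted equally with R, G, B
  (distinct alpha variants of one RGB count as distinct colours); boxes are
  split on the largest count-weighted channel spread at the count median.
  Pixel assignment uses Floyd–Steinberg error diffusion in plain raster
  order (no serpentine) with the classic 7/16, 3/16, 5/16, 1/16 weights.
  When the input already has ≤ 256 distinct colours the palette is exact and
  encoding is lossless (dithering is skipped), which keeps small-palette
  round trips deterministic. The PNG carries the palette alphas as a
  transparency table.

`savings_ratio` reports 1 − encoded/(w·h·4) against a raw 32-bpp bitmap; it
is negative when container overhead exceeds the raw size (tiny noisy
textures).

## Volume pipeline

**XRW container** (this package's dialect; the in-memory `Volume` is its
twin): magic `XRW2`, three little-endian uint32 dims (nx, ny, nz), three
little-endian float32 spacings, then nx·ny·nz little-endian uint16 samples,
x fastest, then y, then z. Write∘read is bit-exact, fuzz-tested.

**Stacking**: slice k of a greyscale image stack becomes plane z = k;
intensities are rescaled affinely over the *whole stack* so global min → 0
and global max → 65535 (a constant stack maps to all zeros). NIfTI input is
routed through the same normalisation. RGB slices collapse to channel means.

**Transfer function**: colour from a named map — `greyscale`, or `hotiron`,
defined here as the black→red→yellow→white piecewise-linear ramp with
breakpoints at 0, ⅓, ⅔, 1 (the conventional hot-iron CLUT; no canonical
table exists) — or any callable; opacity from a linear ramp over an
intensity window [lo, hi] clamped to [0, alpha_max], hence non-decreasing in
intensity. Pre-shading means transfer-function application only; no
directional lighting is baked into slice textures.

**Slice sets**: the RGBA voxel grid is cut, without resampling, into three
orthogonal sets — one texture per voxel plane per axis, texel (u, v) being
exactly the voxel's RGBA. In-plane texel axes follow the cyclic convention
x→(y, z), y→(z, x), z→(x, y). At display time the set whose axis has the
largest |dot| with the view direction is shown (ties break x < y < z; the
choice is invariant under direction negation).

**Opacity equalization**: under back-to-front source-over blending, n slices
of uniform alpha α accumulate to A = 1 − (1 − α)ⁿ — opacity accumulates
exponentially, not linearly, so a volume with unequal axis lengths
composites to different opacities per axis and the slice-set switch jumps
visibly. The rescaling α′ = 1 − (1 − α)^f is exact for this model: factor f
acts as an effective slice-count multiplier, so the default factors
(max dim)/nx, (max dim)/ny, (max dim)/nz equalize a uniform anisotropic
volume identically (the test oracle composites each axis and requires
agreement within 1 %, and verifies the closed form directly). A clipped
linear mode (α·f) is available behind a flag for comparison; it does not
equalize and exists to demonstrate why the exponent form is used. Factors
remain user-overridable because real volumes are not uniform and the ideal
balance is ultimately judged by eye.

The `composite_slices` oracle is an axis-aligned orthographic source-over
compositor (back-to-front in stored ascending-coordinate order; the
front-to-back flag views the stack from the opposite end). It exists for
testing and poster rendering, not as a product renderer.

## Views

Seven default presets, bound to keys 1–7 by the shipped controls script:
perspective views along ±y (front/back), ±x (left/right), ∓z (top/bottom),
plus an oblique view along (1,1,1)/√3; orbit distance defaults to 2 world
units. The `s2views.txt` dialect is block-structured
(`VIEW=name … END`, keys C2C/ROO/ROLL/PROJECTION/LIGHTS and repeated
PART/VISIBLE pairs); parse and serialize are mutually inverse (fuzz-tested),
and parse errors carry line numbers. Applying a view to a tree yields a
full-name→visible map with un-overridden nodes visible; overrides naming
absent nodes are errors. The keyboard-control bindings beyond the seven
views (zoom, roll, swing, autospin) live in the static script asset; only
the view presets are computed.

## PDF embedding

The scene container is this package's deterministic binary dialect
mirroring PRC's structure (assembly tree of named groups, tessellated
entities, textures stored as their encoded JPEG/PNG streams), zlib-
compressed, with a manifest of group names, entity counts and texture
digests. Because no public reference PRC reader exists and only closed
desktop viewers render 3-d PDF, byte-level conformance to external
consumers is not machine-checkable; the authoritative automated contract is
the in-repo round trip — `read_prc(write_prc(t))` structurally equals `t`
(names, order, counts, colours exact; coordinates at float32; texture
streams byte-equal) — plus structural probes of the emitted PDF.

The PDF writer emits PDF 1.7 with one page and exactly one `/Subtype /3D`
annotation: the 3-d stream holds the container bytes with *no* stream filter
(so byte-equality is externally checkable), the poster image is the
annotation's normal appearance (JPEG-backed for opaque posters, flate-raw
otherwise) as well as the page content, each preset becomes a `/3DView`
dictionary (camera-to-world matrix from the preset's direction/distance/
roll, projection, lighting scheme, `/NA` node-visibility array) with the
first preset the default, the controls script is attached via
`/OnInstantiate`, and activation is `/XA` (click, the conservative default
— every reader sees the poster first) or `/PO` (page open). No timestamps
or IDs are written: identical inputs give byte-identical files. The
structural probe (`fig3d.pdfcheck`) is an independently written
xref-walking parser sharing no code with the writer.

Transparent multi-facet meshes are emitted as meshes by default — viewers
are known to draw their facets unsorted, which mottles overlapping
transparent surfaces — with a warning; the `unstructured_transparent` path
stores them as raw facet lists, which viewers draw correctly at a heavy
size/startup cost.

## Synthetic data

Generators are pure functions of their spec (seeded where random):
`gaussian_blob` (bright soft core, peak at the centre voxel) and
`spherical_shell` (bright surface at a stated radius) for volumes;
`uv_sphere_mesh`, `torus_mesh` (closed — every edge shared by exactly two
facets) and `two_part_anatomy` (concentric shell + core as separately named
parts) for surfaces. Default sizes (33³ voxels, 16×16 sphere segments) keep
every test desk-scale. These fixtures exercise the pipeline's contracts —
format round trips, compression invariants, equalization — but contain no
acquisition noise, scanner anisotropy, intensity inhomogeneity or
segmentation artefacts; passing tests therefore validate the *pipeline
mathematics*, not robustness to real acquisition defects, and say nothing
about the perceptual quality of Adobe's closed renderer.

## Numerical choices and degenerate inputs

- Vertex dedupe tolerance defaults to 0 (bitwise); positive tolerances snap
  to a grid of that pitch, trading exactness for robustness to re-exported
  meshes.
- Texture channels are 8-bit; slice alphas are quantized once at texture
  build and once after rescaling (round-to-nearest), bounding equalization
  drift at ~1/255 per stage — inside the 1 % oracle band for the tested
  sizes.
- Billboard and view directions must be non-zero/finite; zero-area quads are
  rejected via the Newell norm.
- Coordinates are carried as float64 in memory and float32 in the container;
  structural equality uses atol 1e-6 with relative slack to absorb the
  float32 round.
- Empty facet collections, zero-size textures, zero-dim volumes, constant
  stacks, and truncated byte streams all have defined behaviour (error or
  documented identity), each under test.

## Known limitations

- Rendering in actual viewers is manual-check-only (closed renderers);
  difference-image/edge-overlay tooling is provided for exactly that
  workflow, and those comparisons are qualitative by design.
- The transparent-mesh sorting defect is a viewer-side issue; this package
  documents and works around it but cannot fix it.
- 3-d-texture volume rendering is not possible in 3-d PDF (no 3-d texture
  support); the slice-set approach is the implemented alternative.
- Foreign PRC files are not read; `read_prc` accepts only this package's
  container.
- OBJ materials/texture coordinates are ignored; surfaces are shaded with
  one nominated solid colour and transparency per part.
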