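"""Minimal deterministic PDF writer for single-figure 3-d documents.

Produces a one-page PDF 1.7 file containing exactly one 3D annotation:

* the annotation's 3-d stream holds the scene container bytes verbatim
  (no stream filter, so external tools can byte-compare the payload);
* the poster image is the annotation's normal appearance (a Form XObject
  drawing a raster image), so viewers without 3-d support — and print —
  show the poster;
* one embedded view dictionary per preset, the first being the default;
* the keyboard-controls/billboard script is attached to run on 3-d
  instantiation;
* activation either on page open ("auto") or on user click ("click",
  the conservative default: every reader is first shown the poster).

The writer emits no timestamps, IDs or library version strings, so identical
inputs yield byte-identical files.
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .prc import PRCPayload
from .texture import TextureImage, classify_texture, encode_texture
from .views import ViewPreset


@dataclass
class Figure3D:
    """Everything needed to emit one interactive 3-d PDF figure."""

    prc: PRCPayload
    poster: TextureImage
    presets: list[ViewPreset] = field(default_factory=list)
    script: str = ""
    activation: str = "click"  # "click" | "auto"

    def __post_init__(self) -> None:
        if self.activation not in ("click", "auto"):
            raise ValidationError("activation must be 'click' or 'auto'")
        if self.poster.width < 1 or self.poster.height < 1:
            raise ValidationError("poster must be non-empty")
        names = [p.name for p in self.presets]
        if len(names) != len(set(names)):
            raise ValidationError("preset names must be unique")


# -- low-level PDF assembly ---------------------------------------------------


class _PDF:
    """Accumulates numbered objects and writes body + xref + trailer."""

    def __init__(self) -> None:
        self.objects: list[bytes | None] = [None]  # 1-based

    def reserve(self) -> int:
        self.objects.append(None)
        return len(self.objects) - 1

    def put(self, num: int, body: bytes) -> None:
        self.objects[num] = body

    def add(self, body: bytes) -> int:
        num = self.reserve()
        self.put(num, body)
        return num

    def stream(self, dict_entries: str, data: bytes) -> bytes:
        return (
            f"<< {dict_entries} /Length {len(data)} >>\nstream\n".encode("latin-1")
            + data
            + b"\nendstream"
        )

    def render(self, root: int) -> bytes:
        out = io.BytesIO()
        out.write(b"%PDF-1.7\n%\xe2\xe3\xcf\xd3\n")
        offsets = [0] * len(self.objects)
        for num, body in enumerate(self.objects):
            if num == 0:
                continue
            if body is None:
                raise ValidationError(f"object {num} reserved but never written")
            offsets[num] = out.tell()
            out.write(f"{num} 0 obj\n".encode("latin-1"))
            out.write(body)
            out.write(b"\nendobj\n")
        xref_at = out.tell()
        out.write(f"xref\n0 {len(self.objects)}\n".encode("latin-1"))
        out.write(b"0000000000 65535 f \n")
        for off in offsets[1:]:
            out.write(f"{off:010d} 00000 n \n".encode("latin-1"))
        out.write(
            (
                f"trailer\n<< /Size {len(self.objects)} /Root {root} 0 R >>\n"
                f"startxref\n{xref_at}\n%%EOF\n"
            ).encode("latin-1")
        )
        return out.getvalue()


def _pdf_string(s: str) -> str:
    esc = s.replace("\\", r"\\").replace("(", r"\(").replace(")", r"\)")
    return f"({esc})"


def _fmt(v: float) -> str:
    return f"{v:.6f}".rstrip("0").rstrip(".") or "0"


def _camera_matrix(preset: ViewPreset, centre=(0.0, 0.0, 0.0)) -> list[float]:
    """12-number camera-to-world matrix for a view preset.

    Convention: the camera sits at ``centre - c2c * roo`` and looks along
    ``c2c`` (toward the centre of orbit); the camera z-axis is the view
    direction, y approximates world +z ("up"), with roll applied about the
    view axis.
    """
    d = np.asarray(preset.c2c, dtype=np.float64)
    up0 = np.array([0.0, 0.0, 1.0])
    if abs(float(np.dot(d, up0))) > 0.999:
        up0 = np.array([0.0, 1.0, 0.0])
    right = np.cross(d, up0)
    right /= np.linalg.norm(right)
    up = np.cross(right, d)
    if preset.roll:
        th = np.deg2rad(preset.roll)
        c, s = np.cos(th), np.sin(th)
        right, up = c * right + s * up, -s * right + c * up
    pos = np.asarray(centre) - d * preset.roo
    return [*right, *up, *d, *pos]


def _view_dict(preset: ViewPreset) -> str:
    mat = " ".join(_fmt(v) for v in _camera_matrix(preset))
    parts = ""
    if preset.parts:
        nodes = " ".join(
            f"<< /Type /3DNode /N {_pdf_string(p.node)} /V {'true' if p.visible else 'false'} >>"
            for p in preset.parts
        )
        parts = f" /NA [ {nodes} ]"
    proj = "/Subtype /P" if preset.projection == "PERSPECTIVE" else "/Subtype /O /OS 1"
    return (
        f"<< /Type /3DView /XN {_pdf_string(preset.name)} "
        f"/IN {_pdf_string(preset.name)} /MS /M /C2W [ {mat} ] "
        f"/CO {_fmt(preset.roo)} /P << {proj} >> "
        f"/LS << /Type /3DLightingScheme /Subtype /{preset.lights} >>{parts} >>"
    )


# -- public API ---------------------------------------------------------------


def embed_pdf(fig: Figure3D, page_size: tuple[float, float] | None = None) -> bytes:
    """Serialize a :class:`Figure3D` to single-page PDF bytes.

    The page (and the annotation rectangle, which fills it) defaults to the
    poster's pixel dimensions in PDF points, capped to 14400 (the PDF page
    limit).
    """
    w, h = float(fig.poster.width), float(fig.poster.height)
    if page_size is not None:
        w, h = (float(v) for v in page_size)
    if not (0 < w <= 14400 and 0 < h <= 14400):
        raise ValidationError(f"page size {w}x{h} outside (0, 14400] points")

    pdf = _PDF()
    catalog = pdf.reserve()
    pages = pdf.reserve()
    page = pdf.reserve()

    # poster image XObject: JPEG when opaque, else flate-compressed raw RGB
    if classify_texture(fig.poster) == "opaque":
        data, _ = encode_texture(fig.poster)
        img_obj = pdf.add(
            pdf.stream(
                f"/Type /XObject /Subtype /Image /Width {fig.poster.width} "
                f"/Height {fig.poster.height} /ColorSpace /DeviceRGB "
                f"/BitsPerComponent 8 /Filter /DCTDecode",
                data,
            )
        )
    else:
        raw = fig.poster.pixels[:, :, :3].tobytes()
        img_obj = pdf.add(
            pdf.stream(
                f"/Type /XObject /Subtype /Image /Width {fig.poster.width} "
                f"/Height {fig.poster.height} /ColorSpace /DeviceRGB "
                f"/BitsPerComponent 8 /Filter /FlateDecode",
                zlib.compress(raw, 9),
            )
        )

    # normal appearance: form XObject drawing the poster over the whole rect
    draw = f"q {_fmt(w)} 0 0 {_fmt(h)} 0 0 cm /Poster Do Q".encode("latin-1")
    appearance = pdf.add(
        pdf.stream(
            f"/Type /XObject /Subtype /Form /BBox [ 0 0 {_fmt(w)} {_fmt(h)} ] "
            f"/Resources << /XObject << /Poster {img_obj} 0 R >> >>",
            draw,
        )
    )

    # 3-d scene stream: raw container bytes, no filter (byte-comparable)
    script_obj = None
    if fig.script:
        script_obj = pdf.add(pdf.stream("", fig.script.encode("latin-1", "replace")))

    view_objs = [pdf.add(_view_dict(p).encode("latin-1")) for p in fig.presets]
    va = ""
    if view_objs:
        refs = " ".join(f"{n} 0 R" for n in view_objs)
        va = f" /VA [ {refs} ] /DV {view_objs[0]} 0 R"
    oninst = f" /OnInstantiate {script_obj} 0 R" if script_obj else ""
    stream_obj = pdf.add(
        pdf.stream(f"/Type /3D /Subtype /PRC{va}{oninst}", fig.prc.bytes)
    )

    activation = "/PO" if fig.activation == "auto" else "/XA"
    dv = f" /3DV {view_objs[0]} 0 R" if view_objs else ""
    annot = pdf.add(
        (
            f"<< /Type /Annot /Subtype /3D /Rect [ 0 0 {_fmt(w)} {_fmt(h)} ] "
            f"/Contents (3D figure) /3DD {stream_obj} 0 R{dv} "
            f"/3DA << /A {activation} >> "
            f"/AP << /N {appearance} 0 R >> /F 4 >>"
        ).encode("latin-1")
    )

    contents = pdf.add(pdf.stream("", draw))
    pdf.put(
        page,
        (
            f"<< /Type /Page /Parent {pages} 0 R /MediaBox [ 0 0 {_fmt(w)} {_fmt(h)} ] "
            f"/Contents {contents} 0 R "
            f"/Resources << /XObject << /Poster {img_obj} 0 R >> >> "
            f"/Annots [ {annot} 0 R ] >>"
        ).encode("latin-1"),
    )
    pdf.put(pages, f"<< /Type /Pages /Kids [ {page} 0 R ] /Count 1 >>".encode("latin-1"))
    pdf.put(catalog, f"<< /Type /Catalog /Pages {pages} 0 R >>".encode("latin-1"))
    return pdf.render(catalog)
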