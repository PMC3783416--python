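"""Predefined camera views and the ``s2views.txt`` dialect.

A 3-d PDF figure ships with a menu of named views.  Each view records a
camera-to-centre direction, an orbit distance, roll, projection and lighting
mode, plus optional per-node visibility overrides — the mechanism used to
show, say, one activation network painted on a cortical surface while hiding
the others.  Seven numbered presets (front/back/left/right/top/bottom/oblique
perspective, bound to keys 1-7 by the shipped JavaScript asset) are generated
by :func:`default_presets`.

Views file dialect (one block per view)::

    VIEW=<name>
    C2C=<x> <y> <z>
    ROO=<distance>
    ROLL=<degrees>            # optional, default 0
    PROJECTION=PERSPECTIVE    # or ORTHOGRAPHIC; optional
    LIGHTS=<tag>              # optional, default CAD
    PART=<full node name>     # repeated; each followed by
    VISIBLE=true|false
    END

Node names in PART lines must match the full names written to the companion
``s2direct.map`` node map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import ParseError, ValidationError
from .scene import ModelTree

PROJECTIONS = ("PERSPECTIVE", "ORTHOGRAPHIC")
DEFAULT_LIGHTS = "CAD"


@dataclass
class PartOverride:
    """Per-node display override inside one view."""

    node: str
    visible: bool
    render_mode: str | None = None
    opacity: float | None = None


@dataclass
class ViewPreset:
    """One named camera pose with optional per-node visibility overrides."""

    name: str
    c2c: tuple[float, float, float]  # camera-to-centre direction, unit
    roo: float = 2.0  # orbit distance, world units
    roll: float = 0.0  # degrees
    projection: str = "PERSPECTIVE"
    lights: str = DEFAULT_LIGHTS
    parts: list[PartOverride] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name or not str(self.name).strip():
            raise ValidationError("view name must be non-empty")
        v = np.asarray(self.c2c, dtype=np.float64)
        if v.shape != (3,) or not np.all(np.isfinite(v)):
            raise ValidationError("C2C must be a finite 3-vector")
        n = float(np.linalg.norm(v))
        if n == 0:
            raise ValidationError("C2C must be non-zero")
        # leave already-unit vectors untouched so serialized text is stable
        self.c2c = tuple(v.tolist()) if abs(n - 1.0) <= 1e-8 else tuple((v / n).tolist())
        if not (float(self.roo) > 0):
            raise ValidationError("orbit distance must be > 0")
        self.roo = float(self.roo)
        self.roll = float(self.roll)
        if self.projection not in PROJECTIONS:
            raise ValidationError(f"projection must be one of {PROJECTIONS}")


_S = 1.0 / math.sqrt(3.0)

#: (name, camera-to-centre direction) for view keys 1-7.  The direction points
#: from the camera toward the model centre, so the front view (camera on -y,
#: by the convention that the model faces -y) looks along +y, etc.
_DEFAULT_VIEWS: tuple[tuple[str, tuple[float, float, float]], ...] = (
    ("Front perspective", (0.0, 1.0, 0.0)),
    ("Back perspective", (0.0, -1.0, 0.0)),
    ("Left perspective", (1.0, 0.0, 0.0)),
    ("Right perspective", (-1.0, 0.0, 0.0)),
    ("Top perspective", (0.0, 0.0, -1.0)),
    ("Bottom perspective", (0.0, 0.0, 1.0)),
    ("Oblique perspective", (_S, _S, _S)),
)


def default_presets(orbit_distance: float = 2.0) -> list[ViewPreset]:
    """The seven standard numbered views (keys 1-7): six axis-aligned
    perspective views plus one oblique perspective view."""
    return [
        ViewPreset(name, c2c, roo=orbit_distance) for name, c2c in _DEFAULT_VIEWS
    ]


def keyboard_controls_script() -> str:
    """The static JavaScript asset implementing the standard keyboard controls
    (zoom, roll, camera swings, autospin) and billboard reorientation."""
    return (
        resources.files("fig3d").joinpath("assets/controls.js").read_text("utf-8")
    )


# -- serialization ------------------------------------------------------------


def serialize_views(presets: list[ViewPreset]) -> str:
    """Write a preset list in the views-file dialect (LF line endings)."""
    blocks = []
    for p in presets:
        lines = [
            f"VIEW={p.name}",
            f"C2C={p.c2c[0]:.9g} {p.c2c[1]:.9g} {p.c2c[2]:.9g}",
            f"ROO={p.roo:.9g}",
        ]
        if p.roll != 0.0:
            lines.append(f"ROLL={p.roll:.9g}")
        if p.projection != "PERSPECTIVE":
            lines.append(f"PROJECTION={p.projection}")
        if p.lights != DEFAULT_LIGHTS:
            lines.append(f"LIGHTS={p.lights}")
        for part in p.parts:
            lines.append(f"PART={part.node}")
            lines.append(f"VISIBLE={'true' if part.visible else 'false'}")
            if part.render_mode is not None:
                lines.append(f"RENDERMODE={part.render_mode}")
            if part.opacity is not None:
                lines.append(f"OPACITY={part.opacity:.9g}")
        lines.append("END")
        blocks.append("\n".join(lines))
    return "\n".join(blocks) + ("\n" if blocks else "")


def parse_views(text: str) -> list[ViewPreset]:
    """Parse views-file text into presets; errors carry the offending line number."""
    presets: list[ViewPreset] = []
    cur: dict | None = None
    cur_part: PartOverride | None = None

    def fail(lineno: int, msg: str):
        raise ParseError(f"views file line {lineno}: {msg}")

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line and line != "END":
            fail(lineno, f"expected KEY=value or END, got {line!r}")
        if line == "END":
            if cur is None:
                fail(lineno, "END outside a VIEW block")
            try:
                presets.append(ViewPreset(**cur))
            except ValidationError as exc:
                fail(lineno, str(exc))
            cur, cur_part = None, None
            continue
        key, _, value = line.partition("=")
        key = key.strip().upper()
        value = value.strip()
        if key == "VIEW":
            if cur is not None:
                fail(lineno, "VIEW block not terminated by END")
            cur = {"name": value, "c2c": (0.0, 1.0, 0.0), "parts": []}
            cur_part = None
            continue
        if cur is None:
            fail(lineno, f"{key} outside a VIEW block")
        try:
            if key == "C2C":
                vals = [float(v) for v in value.split()]
                if len(vals) != 3:
                    fail(lineno, "C2C needs three components")
                cur["c2c"] = tuple(vals)
            elif key == "ROO":
                cur["roo"] = float(value)
            elif key == "ROLL":
                cur["roll"] = float(value)
            elif key == "PROJECTION":
                cur["projection"] = value.upper()
            elif key == "LIGHTS":
                cur["lights"] = value
            elif key == "PART":
                cur_part = PartOverride(value, True)
                cur["parts"].append(cur_part)
            elif key == "VISIBLE":
                if cur_part is None:
                    fail(lineno, "VISIBLE without a preceding PART")
                if value.lower() not in ("true", "false"):
                    fail(lineno, f"VISIBLE must be true or false, got {value!r}")
                cur_part.visible = value.lower() == "true"
            elif key == "RENDERMODE":
                if cur_part is None:
                    fail(lineno, "RENDERMODE without a preceding PART")
                cur_part.render_mode = value
            elif key == "OPACITY":
                if cur_part is None:
                    fail(lineno, "OPACITY without a preceding PART")
                cur_part.opacity = float(value)
            else:
                fail(lineno, f"unknown key {key!r}")
        except ValueError as exc:
            fail(lineno, f"malformed value: {exc}")
    if cur is not None:
        raise ParseError("views file: unterminated VIEW block at end of input")
    return presets


# -- application --------------------------------------------------------------


def apply_view(tree: ModelTree, preset: ViewPreset) -> dict[str, bool]:
    """Resolve a preset's part overrides against a model tree.

    Returns a map from every group full name to its visible flag: nodes
    without an override default to visible.  An override naming a node absent
    from the tree is an error naming the path.
    """
    names = set(tree.full_names())
    vis = {n: True for n in names}
    for part in preset.parts:
        # accept either a bare full name or a dotted path ending in one
        node = part.node.split(".")[-1]
        if node not in names:
            raise ValidationError(
                f"view {preset.name!r}: node {part.node!r} not found in model tree"
            )
        vis[node] = part.visible
    return vis
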