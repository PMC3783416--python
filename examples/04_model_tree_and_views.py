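"""Model tree naming, per-view visibility, and the companion text files.

Mimics a functional-imaging figure: a cortical surface plus several
activation networks, with one named view per network that shows only that
network (the others hidden), the way a reader picks views from the PDF menu.
"""

import numpy as np

from fig3d import (
    FixtureSpec,
    GeometryPayload,
    ModelTree,
    PartOverride,
    ViewPreset,
    apply_view,
    serialize_views,
    synth_mesh,
    write_node_map,
)
from fig3d.mesh_compress import build_indexed_mesh
from fig3d.views import default_presets

tree = ModelTree()
pial_name = tree.register_group("pial")
sphere = synth_mesh(FixtureSpec("uv_sphere_mesh", segments=8))["sphere"]
tree.add_payload(GeometryPayload("indexed_mesh", mesh=build_indexed_mesh(sphere.facets)))

net_names = []
for i in range(3):
    name = tree.register_group("network")  # suffix makes each unique
    net_names.append(name)
print(f"full node names: {pial_name}, {', '.join(net_names)}")
print("node map:")
print(write_node_map(tree), end="")

views = list(default_presets())
for shown in net_names:
    overrides = [PartOverride(pial_name, True)] + [
        PartOverride(n, n == shown) for n in net_names
    ]
    views.append(ViewPreset(f"Network {shown}", (0.0, 1.0, 0.0), parts=overrides))

print("\ns2views.txt block for the first network view:")
print(serialize_views([views[7]]), end="")

vis = apply_view(tree, views[7])
shown = sorted(k for k, v in vis.items() if v)
hidden = sorted(k for k, v in vis.items() if not v)
print(f"\napplying that view: visible={shown} hidden={hidden}")
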