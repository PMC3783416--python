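"""Texture compression policy: JPEG for opaque, dithered palette PNG else.

Shows the two encoding paths on synthetic textures and the size saving
against a raw 32-bit-per-pixel bitmap.
"""

import numpy as np

from fig3d import (
    TextureImage,
    classify_texture,
    decode_texture,
    encode_texture,
    savings_ratio,
)

x = np.linspace(0, 255, 128)
xx, yy = np.meshgrid(x, x)

# an entirely opaque smooth gradient -> JPEG
opaque = TextureImage(
    np.round(np.stack([xx, yy, (xx + yy) / 2, np.full_like(xx, 255)], axis=-1)).astype(np.uint8)
)
data, tag = encode_texture(opaque)
print(f"opaque texture -> {tag}, {len(data)} bytes, "
      f"saving {savings_ratio(opaque, data):.1%} vs raw")

# the same gradient with varying alpha -> palette PNG, max 256 colours,
# Floyd-Steinberg dithered
alpha = 255 * (0.2 + 0.8 * (xx / 255) * (yy / 255))
transparent = TextureImage(
    np.round(np.stack([xx, yy, 255 - xx, alpha], axis=-1)).astype(np.uint8)
)
n_in = len(np.unique(transparent.pixels.reshape(-1, 4), axis=0))
data, tag = encode_texture(transparent)
n_out = len(np.unique(decode_texture(data).pixels.reshape(-1, 4), axis=0))
print(f"{classify_texture(transparent)} texture -> {tag}, {len(data)} bytes, "
      f"saving {savings_ratio(transparent, data):.1%} vs raw")
print(f"distinct RGBA colours: {n_in} -> {n_out} (ceiling 256)")
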