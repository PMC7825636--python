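"""Texture and texture-derivate features of a parametric image.

A patchy two-population map stands in for a heterogeneous parametric
image: GLCM texture (16 gray levels, distances 1-5, four angles) gives
4 first-pass features, and the 15x15-window texture-encoded maps give 16
second-pass (texture-derivate) features.
"""

import numpy as np

from qusresp import averaged_texture, texture_of_texture

rng = np.random.default_rng(42)
homogeneous = rng.normal(size=(60, 60))
patchy = homogeneous.copy()
patchy[:30, :30] += 5.0
patchy[30:, 30:] += 5.0

for tag, img in (("homogeneous", homogeneous), ("patchy", patchy)):
    tex = averaged_texture(img)
    der = texture_of_texture(img)
    print(f"{tag}:")
    print(f"  first-pass  CON={tex.contrast:7.3f} COR={tex.correlation:6.3f} "
          f"ENE={tex.energy:6.4f} HOM={tex.homogeneity:6.4f}")
    print(f"  derivate    CON-CON={der['CON-CON']:7.3f} "
          f"ENE-CON={der['ENE-CON']:7.3f}  ({len(der)} features total)")

print("\nThe patchwork *lowers* first-pass contrast (the wider intensity"
      "\nrange compresses the speckle into fewer gray levels) but raises the"
      "\nsecond-pass contrast of the texture maps: the interfaces dominate"
      "\nthe texture-encoded maps - the 'texture of texture' signal that"
      "\ndistinguishes heterogeneous tumours.")
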