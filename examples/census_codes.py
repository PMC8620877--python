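"""Census codes of receptive fields.

Builds a few 3x3 block patterns, encodes them into 9-bit census codes,
and shows the affine-brightness invariance that makes the codes usable as
detection features.  The code packs one bit per sub-region (1 iff the
sub-region mean is at least the whole-field mean), row-major, top-left in
the least significant bit.
"""

import numpy as np

import corticolumn as cc
from corticolumn.census import Region

patterns = {
    "middle bar": [[0, 0, 0], [1, 1, 1], [0, 0, 0]],
    "left column": [[1, 0, 0], [1, 0, 0], [1, 0, 0]],
    "corner": [[1, 1, 1], [1, 0, 0], [1, 0, 0]],
    "diagonal": [[1, 0, 0], [0, 1, 0], [0, 0, 1]],
}

full = Region(0, 0, 30, 30)
for name, pattern in patterns.items():
    img = cc.pattern_image(np.array(pattern))
    code = cc.encode(cc.build_integral(img), full)
    print(f"{name:12s} -> C = {code:3d}  (bits {code:09b})")

# the code survives any positive gain and offset of the brightness
rng = np.random.default_rng(0)
img = rng.uniform(10, 200, (30, 30))
c0 = cc.encode(cc.build_integral(img), full)
c1 = cc.encode(cc.build_integral(3.7 * img + 55.0), full)
print(f"\nrandom field: code {c0} == {c1} after gain 3.7, offset 55 -> "
      f"{'invariant' if c0 == c1 else 'changed'}")

# dense code map: overlapping receptive fields inside an aperture
cm = cc.code_map(cc.build_integral(img), Region(0, 0, 30, 30), (9, 9), 3)
print(f"\ncode map of 9x9 fields at stride 3 over a 30x30 aperture: "
      f"{cm.codes.shape[0]}x{cm.codes.shape[1]} codes")
print(cm.codes)
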