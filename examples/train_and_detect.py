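"""Train a digit column and detect the digit in a cluttered scene.

Renders a jittered set of digit-3 windows and textured backgrounds, grows
a cascade column, then scans a scene with one planted glyph.  Printed per
stage: weak count, threshold, false-accept rate on the stage's negatives,
and the empirical per-window false-accept rate after background
re-scanning.  The detection line gives the averaged box, its mean stage
margin and how many raw window accepts support it.
"""

import numpy as np

import corticolumn as cc
from corticolumn.cascade import StageGoals, cascade_train
from corticolumn.scanning import detect

positives, _ = cc.render_glyph_set(cc.GlyphSpec(seed=7), 500, digits=(3,))
backgrounds = []
for i, style in enumerate(("noise", "gradient", "texture")):
    backgrounds += cc.render_backgrounds((128, 128), style, 5, seed=1 + i)

column = cascade_train(positives, backgrounds, StageGoals(), seed=11,
                       object_type="Digit3")
print(f"trained column '{column.object_type}': {column.num_stages} stages")
for h in column.history:
    print(f"  stage {h['stage']}: {h['n_weaks']} weaks, theta={h['theta']:.3f}, "
          f"stage FAR={h['stage_far']:.3f}, scan FAR={h['far_empirical']:.2e}")

scene = cc.render_backgrounds((120, 120), "noise", 1, seed=33)[0].copy()
glyph = cc.render_glyph(3, cc.GlyphSpec(seed=7), np.random.default_rng(5))
scene[50:74, 30:54] = glyph  # plant the digit at (30, 50)

for d in detect(scene, column, stride=1):
    print(f"detection: box=({d.x},{d.y},{d.w},{d.h}) score={d.score:.2f} "
          f"support={d.support}  (planted at (30,50,24,24))")
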