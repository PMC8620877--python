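"""Inspect a trained column as a 7-layer cortical-column model.

Trains a small column, prints its layer census (how many neuron-like
elements realize each functional layer), saves/reloads the XML model
file, and traces the column's activity on an accepted window — which
weak classifiers fired, which stages passed, whether the output neuron
went active.
"""

import corticolumn as cc
from corticolumn.cascade import StageGoals, cascade_train
from corticolumn.column import (
    activation_trace,
    layer_census,
    load_column_xml,
    render_activity,
    save_column_xml,
)

positives, _ = cc.render_glyph_set(cc.GlyphSpec(seed=3), 300, digits=(5,))
backgrounds = cc.render_backgrounds((96, 96), "noise", 6, seed=40)
column = cascade_train(positives, backgrounds, StageGoals(max_stages=5),
                       seed=5, object_type="Digit5")

census = layer_census(column)
print("layer census (elements per functional layer):")
for role in census.roles:
    print(f"  {role:16s} {census.counts[role]}")
print(f"NumStages = {column.num_stages}, NumSensor(K) = {census.num_sensors}")

save_column_xml(column, "/tmp/Digit5.xml")
reloaded = load_column_xml("/tmp/Digit5.xml")
print(f"\nmodel file round-trip: {reloaded.num_stages} stages, "
      f"object type {reloaded.object_type!r}")

glyph = cc.render_glyph(5, cc.GlyphSpec(seed=3))
trace = activation_trace(column, glyph)
print(f"\ntrace on a clean glyph: accepted={trace.accepted}, "
      f"stages evaluated={trace.stages_evaluated}")
for sa in trace.stages:
    print(f"  stage {sa.stage}: score={sa.score:.3f} > theta={sa.theta:.3f}? "
          f"{sa.fired}; firing weaks {sa.active_weaks}")
render_activity(trace, column).save("/tmp/activity.png")
print("2D activity render written to /tmp/activity.png")
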