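"""Build the synthetic head atlas and apply graded atrophy.

Paints the 14-region ellipsoid layout, then emulates disease by eroding the
hippocampi (eroded voxels become CSF-like fill) and dilating the lateral
ventricles (which consume neighboring white matter).  Prints region volumes
before and after: erosion shrinks the hippocampus, dilation grows the
ventricle, and the total labeled volume is conserved.
"""

import proximark as pm

spec = pm.default_phantom_spec(grid_shape=(48, 48, 48))
atlas = pm.build_atlas(spec)

atrophied = pm.apply_atrophy(
    atlas,
    {"Left-Hippocampus": -2, "Right-Hippocampus": -2,
     "Left-Lateral-Ventricle": +1, "Right-Lateral-Ventricle": +1},
    fill_label="CSF",
)

before = pm.region_volumes(atlas)
after = pm.region_volumes(atrophied)
print(f"{'region':32s} {'before mm^3':>12s} {'after mm^3':>12s}")
for name in ("Left-Hippocampus", "Left-Lateral-Ventricle", "Left-Cerebral-White-Matter", "CSF"):
    print(f"{name:32s} {before[name]:12.0f} {after[name]:12.0f}")

total_before = sum(before.values())
total_after = sum(after.values())
print(f"\ntotal labeled volume conserved: {total_before:.0f} == {total_after:.0f} mm^3")
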