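"""The non-symmetric surface-connectivity marker.

For each region, the percentage of its exposed voxel faces (6-neighbor faces
with a different label on the other side) shared with every other region.
Each row is normalized by that region's own surface, so a small region can be
heavily connected to a large neighbor while the large neighbor barely notices
it — the matrix is non-symmetric by construction.
"""

import proximark as pm

spec = pm.default_phantom_spec(grid_shape=(48, 48, 48))
atlas = pm.build_atlas(spec)
grouping = pm.load_groupings("phantom")["brain"]
cm = pm.connectivity_matrix(atlas, grouping)

idx = {name: i for i, name in enumerate(cm.regions)}
pairs = [
    ("Left-Hippocampus", "Left-Cerebral-White-Matter"),
    ("Left-Lateral-Ventricle", "Left-Cerebral-White-Matter"),
    ("Left-Thalamus-Proper", "Left-Cerebral-White-Matter"),
]
print(f"{'region A':26s} {'region B':28s} {'A->B %':>8s} {'B->A %':>8s}")
for a, b in pairs:
    print(f"{a:26s} {b:28s} {cm.values[idx[a], idx[b]]:8.2f} {cm.values[idx[b], idx[a]]:8.2f}")

print("\nEach row sums (with background contact) to 100% of that region's surface;")
sf = pm.surface_faces(atlas, "Left-Hippocampus")
print(f"e.g. Left-Hippocampus has {sf.total_faces} exposed faces, "
      f"{sum(v for k, v in sf.contact_faces.items() if k != 0)} of them shared with other regions.")
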