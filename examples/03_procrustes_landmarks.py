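"""Procrustes landmark marker: region centroids aligned across subjects.

Each subject contributes the centroid of every region; generalized Procrustes
analysis removes translation, size and orientation, leaving a per-subject
shape vector.  Here a tiny cohort with hippocampal atrophy in half the
subjects shows up as a displacement of the aligned hippocampal landmarks.
"""

import numpy as np

import proximark as pm
from proximark.regionstats import all_centroids
from proximark.shapes import LandmarkSet, gpa, save_landmarks_tsv

spec = pm.default_phantom_spec(grid_shape=(48, 48, 48))
grouping = pm.load_groupings("phantom")["brain"]

sets, groups = [], []
for record, vols in pm.iter_cohort(
    spec, pm.default_atrophy_spec(), {"NC": 6, "AD": 6}, seed=3, timepoints=("bl",)
):
    coords = all_centroids(vols["bl"], grouping.region_names)
    sets.append(LandmarkSet(grouping.region_names, coords))
    groups.append(record.diagnosis)

result = gpa(sets)
print(f"GPA converged in {result.n_iter} iterations "
      f"(residual sum of squares {result.objective_history[-1]:.4f})")

k = grouping.region_names.index("Left-Hippocampus")
aligned = np.stack([s.coords[k] for s in result.aligned])
nc = aligned[[g == "NC" for g in groups]].mean(axis=0)
ad = aligned[[g == "AD" for g in groups]].mean(axis=0)
shift = np.linalg.norm(nc - ad)
print(f"aligned Left-Hippocampus centroid, NC mean: {np.round(nc, 4)}")
print(f"aligned Left-Hippocampus centroid, AD mean: {np.round(ad, 4)}")
print(f"group displacement in shape space: {shift:.4f} "
      "(atrophy moves the landmark relative to the rest of the brain)")

save_landmarks_tsv(result.mean_shape, "mean_shape.tsv")
print("mean shape written to mean_shape.tsv")
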