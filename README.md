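# proximark

Inter-region **proximity markers** from labeled brain volumes, with a
PLS+LDA classification pipeline and a synthetic atrophy phantom.

Neurodegeneration does not only shrink individual structures — it changes how
brain regions sit relative to one another: sulci widen, ventricles dilate,
and the surfaces of neighboring structures gain or lose contact.  `proximark`
turns an integer-labeled parcellation volume (e.g. a FreeSurfer `aseg`-style
segmentation stored as NIfTI) into per-subject markers of that relative
geometry and evaluates how well they separate diagnostic groups
(normal controls NC, mild cognitive impairment MCI, Alzheimer's disease AD),
including MCI subjects who later convert (MCI-c vs MCI-nc).

## Markers

* **Surface connectivity** — for region *i* with discrete surface *F<sub>i</sub>*
  (the number of its exposed voxel faces, a face being exposed when the
  6-neighbor across it carries a different label), the entry

  *S<sub>ij</sub>* = 100 · *F<sub>ij</sub>* / *F<sub>i</sub>*

  is the percentage of region *i*'s own surface shared with region *j*.  Rows
  are normalized by each region's own surface, so the K×K matrix is
  **non-symmetric**; an entry of 0 means the two regions share no faces.  The
  feature vector is the K(K−1) off-diagonal entries.
* **Procrustes landmarks** — the center of mass **c** of each region, computed
  either as the mean of voxel centers or, equivalently, by the divergence
  theorem as a sum over exposed faces,

  **c**·**e**<sub>d</sub> = 1/(2V) Σ<sub>faces</sub> ∫<sub>A<sub>i</sub></sub> (**x**·**e**<sub>d</sub>)² (**n**<sub>i</sub>·**e**<sub>d</sub>),

  then aligned across subjects by full-similarity generalized Procrustes
  analysis (translation, scaling, rotation; reflections excluded).  The
  aligned 3K coordinates are the shape feature vector.
* **Volume fractions** — whole-brain volume (all intracranial regions except
  CSF-like/vessel labels) and hippocampal volume, each divided by the
  intracranial volume.

Markers are computed **within** each subject's own volume (no inter-subject
registration), so they are comparable across timepoints; longitudinal *delta*
markers are month-12 minus baseline differences.

## Classification pipeline

Per contrast (NC–AD, NC–MCI, MCI–AD, MCI-c–MCI-nc): optional covariate
residualization of the feature columns (each covariate gated by a Pearson
correlation test at p < 0.05 on training rows; age/sex or baseline volume),
PLS dimensionality reduction (NIPALS, 10 components, class code ±1 as the
response), and a two-class linear discriminant on the PLS scores.  Evaluation
is **leave-one-of-each-class-out** cross-validation — every fold withholds one
subject per class, all fitting (including the Procrustes mean shape) uses the
training fold only — with the Mann-Whitney AUC and a Wilcoxon rank-sum test
on the out-of-fold decision scores.

## The phantom

Cohort studies of this kind use restricted clinical MRI, so the package ships
a synthetic stand-in: a 14-region ellipsoid head atlas in which atrophy is
emulated by integer morphological steps — erosion of gray-matter structures
(eroded voxels relabeled to CSF) and dilation of the lateral ventricles —
graded NC < MCI < AD, progressing from baseline to month 12, with converters
receiving the AD-rate increment.  Subject variability comes from global scale
jitter, rigid shifts, an age-linked extra cortical erosion and random flips
of boundary voxels (segmentation noise).  Everything is reproducible from a
single seed.

## Worked example

```bash
python examples/01_phantom_atlas.py
```

```
region                            before mm^3   after mm^3
Left-Hippocampus                          354           50
Left-Lateral-Ventricle                    292          543
Left-Cerebral-White-Matter               4180         3990
CSF                                     23206        23814

total labeled volume conserved: 45104 == 45104 mm^3
```

Two erosion layers shrink the hippocampus from 354 to 50 mm³ (the removed
voxels become CSF), one dilation layer grows the ventricle at the expense of
white matter, and no labeled voxel is created or destroyed.  The connectivity
marker sees the same event from the surface side
(`examples/02_surface_connectivity.py`):

```
region A                   region B                       A->B %   B->A %
Left-Hippocampus           Left-Cerebral-White-Matter      57.63     8.48
Left-Lateral-Ventricle     Left-Cerebral-White-Matter      78.98    10.76
```

57.6 % of the hippocampal surface touches white matter, but only 8.5 % of the
much larger white-matter surface touches the hippocampus — the non-symmetry
that row-wise normalization creates.  `examples/03_procrustes_landmarks.py`
shows the aligned-landmark marker and
`examples/04_classification_experiment.py` runs the full grid on a small
cohort, printing an AUC / rank-sum table per contrast and marker.

The same workflow is available from the shell:

```bash
proximark simulate --out cohort --n-per-class 10 --n-converters 5 --seed 1
proximark extract  --cohort cohort --out tables
proximark classify --tables tables --out results.tsv --seed 1
proximark report   --results results.tsv
```

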