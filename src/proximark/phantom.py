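"""Synthetic labeled head phantom with class-dependent atrophy.

The study population this package targets (normal controls, mild cognitive
impairment, Alzheimer's disease) cannot be redistributed, so every downstream
stage is exercised on a phantom: a multi-region labeled head volume built from
painted ellipsoids, with neurodegeneration emulated by integer morphological
steps — erosion of gray-matter structures (eroded voxels relabeled to a
CSF-like fill region, emulating widened sulci and more inter-region fluid) and
dilation of the lateral ventricles (consuming neighboring tissue voxels).

Atrophy is graded by diagnosis (NC < MCI < AD), progresses from baseline to
month 12, and MCI converters receive the AD-rate month-12 increment so the
longitudinal delta markers carry a real converter signal.  Per-subject
anatomical variability comes from a global scale jitter, a small rigid shift
of the whole layout, an age-linked extra cortical erosion (so age correlates
with the features and the covariate-adjustment path is exercised), and random
flips of inter-region boundary voxels emulating segmentation noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import LabeledVolume, save_labeled_volume

__all__ = [
    "RegionEllipsoid",
    "PhantomSpec",
    "AtrophySpec",
    "CohortNoise",
    "SubjectRecord",
    "PhantomError",
    "default_phantom_spec",
    "default_atrophy_spec",
    "null_atrophy_spec",
    "build_atlas",
    "apply_atrophy",
    "flip_boundary_voxels",
    "simulate_subject",
    "iter_cohort",
    "generate_cohort",
    "phantom_fraction_defs",
]

DIAGNOSES = ("NC", "MCI", "AD")


class PhantomError(ValueError):
    """Raised when a phantom cannot be built as specified."""


@dataclass(frozen=True)
class RegionEllipsoid:
    """One painted region: name, label id, center and semi-axes as grid fractions."""

    name: str
    label: int
    center_frac: tuple[float, float, float]
    semi_axes_frac: tuple[float, float, float]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the synthetic head atlas.

    Regions are painted in list order (painter's algorithm): later regions
    overwrite earlier ones, so the CSF shell comes first and small deep nuclei
    last.  Left/right paired regions must be mirror images across the
    mid-sagittal plane (axis 0 midplane).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    region_layout: tuple[RegionEllipsoid, ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        labels = [r.label for r in self.region_layout]
        if any(l <= 0 for l in labels):
            raise PhantomError("label ids must be positive (0 is background)")
        if len(set(labels)) != len(labels):
            raise PhantomError("label ids must be unique")
        by_name = {r.name: r for r in self.region_layout}
        for r in self.region_layout:
            if r.name.startswith("Left-"):
                other = by_name.get("Right-" + r.name[len("Left-"):])
                if other is None:
                    raise PhantomError(f"{r.name} has no Right- counterpart")
                mirrored = (1.0 - other.center_frac[0],) + tuple(other.center_frac[1:])
                if not (
                    np.allclose(r.center_frac, mirrored)
                    and np.allclose(r.semi_axes_frac, other.semi_axes_frac)
                ):
                    raise PhantomError(f"{r.name}/{other.name} are not mirror-symmetric")

    @property
    def label_names(self) -> dict[int, str]:
        return {r.label: r.name for r in self.region_layout}


@dataclass(frozen=True)
class AtrophySpec:
    """Per-class, per-region signed morphology steps.

    ``class_steps`` are cumulative baseline steps per diagnosis (negative =
    erode that many 6-connectivity boundary layers, relabeling removed voxels
    to ``fill_region``; positive = dilate, consuming neighboring non-background
    voxels).  ``m12_increment`` is added on top at month 12; MCI converters
    receive the increment of ``converter_increment_class`` (AD by default)
    instead of the MCI one.  ``age_slope`` erodes ``age_regions`` by one extra
    step per ``10/age_slope`` years above ``age_ref``, inducing an age-feature
    correlation.
    """

    class_steps: Mapping[str, Mapping[str, int]] = field(default_factory=dict)
    m12_increment: Mapping[str, Mapping[str, int]] = field(default_factory=dict)
    converter_increment_class: str = "AD"
    fill_region: str = "CSF"
    min_voxels: int = 1
    age_slope: float = 0.0
    age_ref: float = 65.0
    age_regions: tuple[str, ...] = ("Left-Cerebral-Cortex", "Right-Cerebral-Cortex")

    def __post_init__(self) -> None:
        for d in (self.class_steps, self.m12_increment):
            for steps in d.values():
                for region, step in steps.items():
                    if int(step) != step:
                        raise PhantomError(f"step for {region!r} must be an integer")

    def steps_for(self, diagnosis: str, timepoint: str, converter: bool, age: float) -> dict[str, int]:
        """Cumulative signed steps for one subject-timepoint."""
        steps: dict[str, int] = dict(self.class_steps.get(diagnosis, {}))
        if timepoint == "m12":
            inc_class = (
                self.converter_increment_class
                if diagnosis == "MCI" and converter
                else diagnosis
            )
            for region, step in self.m12_increment.get(inc_class, {}).items():
                steps[region] = steps.get(region, 0) + int(step)
        if self.age_slope > 0:
            extra = max(0, math.floor(self.age_slope * (age - self.age_ref) / 10.0))
            for region in self.age_regions:
                if extra:
                    steps[region] = steps.get(region, 0) - extra
        return {r: s for r, s in steps.items() if s != 0}


@dataclass(frozen=True)
class CohortNoise:
    """Per-subject nuisance variability of the cohort generator."""

    scale_sigma: float = 0.03        # s.d. of the global size factor
    shift_max_voxels: float = 0.5    # uniform rigid shift per axis
    boundary_flip_frac: float = 0.005  # fraction of boundary voxels flipped
    age_mean: float = 73.0
    age_sd: float = 6.0
    age_range: tuple[float, float] = (55.0, 90.0)


@dataclass(frozen=True)
class SubjectRecord:
    id: str
    diagnosis: str
    converter: bool
    age_bl: float
    sex: str

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise PhantomError(f"diagnosis must be one of {DIAGNOSES}")
        if self.converter and self.diagnosis != "MCI":
            raise PhantomError("converter flag is only meaningful for MCI subjects")


def default_phantom_spec(
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> PhantomSpec:
    """The 14-region head layout: CSF shell, cortex, white matter, lateral
    ventricles, thalami, hippocampi, amygdalae (left/right each) and brain stem."""

    def lr(name: str, label_l: int, label_r: int, cx: float, rest: tuple[float, float],
           semi: tuple[float, float, float]) -> list[RegionEllipsoid]:
        return [
            RegionEllipsoid(f"Left-{name}", label_l, (cx, *rest), semi),
            RegionEllipsoid(f"Right-{name}", label_r, (1.0 - cx, *rest), semi),
        ]

    layout: list[RegionEllipsoid] = [
        RegionEllipsoid("CSF", 1, (0.5, 0.5, 0.5), (0.46, 0.46, 0.46)),
        *lr("Cerebral-Cortex", 2, 3, 0.30, (0.50, 0.55), (0.18, 0.38, 0.34)),
        *lr("Cerebral-White-Matter", 4, 5, 0.30, (0.50, 0.55), (0.13, 0.31, 0.26)),
        *lr("Lateral-Ventricle", 6, 7, 0.38, (0.48, 0.57), (0.05, 0.16, 0.08)),
        *lr("Thalamus-Proper", 8, 9, 0.42, (0.44, 0.46), (0.055, 0.08, 0.065)),
        *lr("Hippocampus", 10, 11, 0.32, (0.36, 0.40), (0.08, 0.13, 0.08)),
        *lr("Amygdala", 12, 13, 0.32, (0.24, 0.42), (0.05, 0.055, 0.05)),
        RegionEllipsoid("Brain-Stem", 14, (0.5, 0.42, 0.22), (0.06, 0.07, 0.15)),
    ]
    return PhantomSpec(grid_shape=grid_shape, spacing_mm=spacing_mm, region_layout=tuple(layout))


def default_atrophy_spec() -> AtrophySpec:
    """Graded atrophy NC < MCI < AD with longitudinal AD progression.

    AD: hippocampal erosion of 2 boundary layers plus ventricular dilation of
    1 layer at baseline, with one further layer of each between baseline and
    month 12.  MCI: half the AD baseline effect (one hippocampal layer) and no
    month-12 increment — non-converters are modeled as longitudinally stable,
    while converters receive the AD increment.
    """
    hippo = ("Left-Hippocampus", "Right-Hippocampus")
    vent = ("Left-Lateral-Ventricle", "Right-Lateral-Ventricle")
    return AtrophySpec(
        class_steps={
            "NC": {},
            "MCI": {h: -1 for h in hippo},
            "AD": {**{h: -2 for h in hippo}, **{v: +1 for v in vent}},
        },
        m12_increment={
            "NC": {},
            "MCI": {},
            "AD": {**{h: -1 for h in hippo}, **{v: +1 for v in vent}},
        },
        age_slope=0.5,
    )


def null_atrophy_spec() -> AtrophySpec:
    """No class effect, no longitudinal change, no age link (null phantom)."""
    return AtrophySpec(age_slope=0.0)


# ---------------------------------------------------------------------------
# atlas construction
# ---------------------------------------------------------------------------


def build_atlas(
    spec: PhantomSpec,
    *,
    scale: float = 1.0,
    shift_voxels: Sequence[float] = (0.0, 0.0, 0.0),
) -> LabeledVolume:
    """Paint the region ellipsoids onto the grid in layout order.

    ``scale`` multiplies every semi-axis (global head-size jitter) and
    ``shift_voxels`` translates all centers rigidly.  A region that ends up
    with no voxels — painted outside the grid or fully overpainted by a later
    region — raises :class:`PhantomError` naming it.
    """
    shape = np.asarray(spec.grid_shape, dtype=int)
    labels = np.zeros(tuple(shape), dtype=np.int16)
    shift = np.asarray(shift_voxels, dtype=float)
    for region in spec.region_layout:
        center = np.asarray(region.center_frac) * shape + shift
        semi = np.maximum(np.asarray(region.semi_axes_frac) * shape * scale, 1e-9)
        lo = np.maximum(np.floor(center - semi).astype(int), 0)
        hi = np.minimum(np.ceil(center + semi).astype(int) + 1, shape)
        if np.any(lo >= hi):
            raise PhantomError(f"region {region.name!r} lies outside the grid")
        grids = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        q = sum(((g + 0.5 - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
        mask = q <= 1.0
        if not mask.any():
            raise PhantomError(f"region {region.name!r} contains no voxel centers")
        sub = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub[mask] = region.label
    counts = np.bincount(labels.ravel(), minlength=max(spec.label_names) + 1)
    for lab, name in spec.label_names.items():
        if counts[lab] == 0:
            raise PhantomError(f"region {name!r} was fully overpainted by later regions")
    return LabeledVolume(labels=labels, spacing_mm=spec.spacing_mm, label_names=spec.label_names)


_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def apply_atrophy(
    vol: LabeledVolume,
    steps: Mapping[str | int, int],
    fill_label: str | int,
    min_voxels: int = 1,
) -> LabeledVolume:
    """Erode/dilate regions by integer numbers of 6-connectivity layers.

    A step of ``-n`` removes the n outermost boundary layers of the region
    (voxels outside the grid count as background, so surfaces at the
    field-of-view edge erode too); removed voxels are relabeled to
    ``fill_label``.  A step of ``+n`` grows the region by n layers, consuming
    only neighboring non-background voxels.  Regions are processed in the
    mapping's order.  The total non-background voxel count is conserved
    whenever ``fill_label`` is not background.
    """
    labels = vol.labels.copy()
    fill = vol.resolve(fill_label)
    for region, step in steps.items():
        lab = vol.resolve(region)
        step = int(step)
        if step == 0:
            continue
        mask = labels == lab
        if step < 0:
            if not mask.any():
                raise PhantomError(f"cannot erode empty region {region!r}")
            kept = ndimage.binary_erosion(mask, _STRUCT6, iterations=-step, border_value=0)
            if kept.sum() < min_voxels:
                raise PhantomError(
                    f"eroding region {region!r} by {-step} layers leaves "
                    f"{int(kept.sum())} voxels (< min {min_voxels})"
                )
            labels[mask & ~kept] = fill
        else:
            grown = ndimage.binary_dilation(mask, _STRUCT6, iterations=step)
            labels[grown & ~mask & (labels != 0)] = lab
    return LabeledVolume(labels=labels, spacing_mm=vol.spacing_mm, label_names=vol.label_names)


def flip_boundary_voxels(
    vol: LabeledVolume, frac: float, rng: np.random.Generator
) -> LabeledVolume:
    """Segmentation-noise model: relabel a fraction of boundary voxels.

    Candidates are non-background voxels with at least one differing in-grid
    6-neighbor; each selected voxel takes the label of one of its differing
    neighbors, chosen uniformly.  Flips are simultaneous (computed from the
    input labeling).
    """
    if frac <= 0:
        return vol
    labels = vol.labels.copy()
    pad = np.pad(labels, 1, constant_values=-1)
    shifts = [
        pad[2:, 1:-1, 1:-1], pad[:-2, 1:-1, 1:-1],
        pad[1:-1, 2:, 1:-1], pad[1:-1, :-2, 1:-1],
        pad[1:-1, 1:-1, 2:], pad[1:-1, 1:-1, :-2],
    ]
    neighbors = np.stack(shifts, axis=-1)  # (X, Y, Z, 6)
    differs = (neighbors != labels[..., None]) & (neighbors >= 0)
    candidate = differs.any(axis=-1) & (labels > 0)
    cand_idx = np.flatnonzero(candidate.ravel())
    n_flip = int(round(frac * cand_idx.size))
    if n_flip == 0:
        return vol
    chosen = rng.choice(cand_idx, size=n_flip, replace=False)
    nb = neighbors.reshape(-1, 6)[chosen]
    ok = differs.reshape(-1, 6)[chosen]
    # pick the k-th valid neighbor, k uniform per row
    counts = ok.sum(axis=1)
    k = (rng.random(n_flip) * counts).astype(int) + 1
    cum = np.cumsum(ok, axis=1)
    sel = np.argmax((cum == k[:, None]) & ok, axis=1)
    flat = labels.ravel()
    flat[chosen] = nb[np.arange(n_flip), sel]
    return LabeledVolume(
        labels=flat.reshape(labels.shape), spacing_mm=vol.spacing_mm, label_names=vol.label_names
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def simulate_subject(
    spec: PhantomSpec,
    atrophy: AtrophySpec,
    record: SubjectRecord,
    rng: np.random.Generator,
    noise: CohortNoise = CohortNoise(),
    timepoints: Sequence[str] = ("bl", "m12"),
) -> dict[str, LabeledVolume]:
    """Labeled volumes for one subject at the requested timepoints.

    Subject pose (scale jitter and rigid shift) is drawn once so both
    timepoints share the same anatomy; atrophy is applied after posing, and
    boundary noise is drawn independently per timepoint (segmentations of the
    same brain at two visits differ).
    """
    scale = 1.0 + noise.scale_sigma * float(np.clip(rng.standard_normal(), -2.5, 2.5))
    shift = rng.uniform(-noise.shift_max_voxels, noise.shift_max_voxels, size=3)
    base = build_atlas(spec, scale=scale, shift_voxels=shift)
    out: dict[str, LabeledVolume] = {}
    for tp in timepoints:
        steps = atrophy.steps_for(record.diagnosis, tp, record.converter, record.age_bl)
        vol = apply_atrophy(base, steps, atrophy.fill_region, atrophy.min_voxels) if steps else base
        out[tp] = flip_boundary_voxels(vol, noise.boundary_flip_frac, rng)
    return out


def _make_records(
    n_per_class: Mapping[str, int],
    n_converters: int,
    rng: np.random.Generator,
    noise: CohortNoise,
) -> list[SubjectRecord]:
    records = []
    for diagnosis in DIAGNOSES:
        n = int(n_per_class.get(diagnosis, 0))
        if n == 0:
            continue
        if n < 2:
            raise PhantomError(f"need at least 2 subjects per used class, got {n} for {diagnosis}")
        n_conv = min(n_converters, n) if diagnosis == "MCI" else 0
        for i in range(n):
            age = float(np.clip(noise.age_mean + noise.age_sd * rng.standard_normal(), *noise.age_range))
            records.append(
                SubjectRecord(
                    id=f"{diagnosis.lower()}{i:03d}",
                    diagnosis=diagnosis,
                    converter=i < n_conv,
                    age_bl=round(age, 1),
                    sex="F" if rng.random() < 0.5 else "M",
                )
            )
    return records


def iter_cohort(
    spec: PhantomSpec,
    atrophy: AtrophySpec,
    n_per_class: Mapping[str, int],
    seed: int,
    *,
    n_converters: int = 0,
    noise: CohortNoise = CohortNoise(),
    timepoints: Sequence[str] = ("bl", "m12"),
) -> Iterator[tuple[SubjectRecord, dict[str, LabeledVolume]]]:
    """Yield (record, {timepoint: volume}) for a fully seed-determined cohort.

    Demographics come from one stream and each subject gets an independent
    child stream, so the cohort is reproducible subject-by-subject.
    """
    ss = np.random.SeedSequence(seed)
    demo_rng = np.random.default_rng(ss.spawn(1)[0])
    records = _make_records(n_per_class, n_converters, demo_rng, noise)
    child_seeds = ss.spawn(len(records) + 1)[1:]
    for record, child in zip(records, child_seeds):
        rng = np.random.default_rng(child)
        yield record, simulate_subject(spec, atrophy, record, rng, noise, timepoints)


def generate_cohort(
    spec: PhantomSpec,
    atrophy: AtrophySpec,
    n_per_class: Mapping[str, int],
    seed: int,
    out_dir: str | Path,
    *,
    n_converters: int = 0,
    noise: CohortNoise = CohortNoise(),
    timepoints: Sequence[str] = ("bl", "m12"),
) -> pd.DataFrame:
    """Write one NIfTI per subject-timepoint plus ``manifest.csv`` and
    ``labels.json`` (label id -> region name) to ``out_dir``; returns the
    manifest.  Rerunning with the same seed reproduces identical label arrays.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for record, vols in iter_cohort(
        spec, atrophy, n_per_class, seed,
        n_converters=n_converters, noise=noise, timepoints=timepoints,
    ):
        for tp, vol in vols.items():
            path = out_dir / f"{record.id}_{tp}.nii.gz"
            save_labeled_volume(vol, path)
            rows.append({**asdict(record), "timepoint": tp, "path": str(path)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    (out_dir / "labels.json").write_text(
        json.dumps({int(k): v for k, v in spec.label_names.items()}, indent=1)
    )
    return manifest


def load_phantom_config(source: str | Path = "default") -> tuple[PhantomSpec, AtrophySpec, CohortNoise]:
    """Load a phantom + atrophy + noise configuration from JSON.

    ``source`` is a path, or ``"default"`` for the shipped configuration
    (identical to :func:`default_phantom_spec` / :func:`default_atrophy_spec`).
    """
    from importlib import resources

    if source == "default":
        text = resources.files("proximark.data").joinpath("phantom_default.json").read_text()
    else:
        text = Path(source).read_text()
    cfg = json.loads(text)
    spec = PhantomSpec(
        grid_shape=tuple(cfg["grid_shape"]),
        spacing_mm=tuple(cfg.get("spacing_mm", (1.0, 1.0, 1.0))),
        region_layout=tuple(
            RegionEllipsoid(r["name"], int(r["label"]),
                            tuple(r["center_frac"]), tuple(r["semi_axes_frac"]))
            for r in cfg["regions"]
        ),
        rng_seed=int(cfg.get("rng_seed", 0)),
    )
    a = cfg.get("atrophy", {})
    atrophy = AtrophySpec(
        class_steps=a.get("class_steps", {}),
        m12_increment=a.get("m12_increment", {}),
        converter_increment_class=a.get("converter_increment_class", "AD"),
        fill_region=a.get("fill_region", "CSF"),
        min_voxels=int(a.get("min_voxels", 1)),
        age_slope=float(a.get("age_slope", 0.0)),
        age_ref=float(a.get("age_ref", 65.0)),
        age_regions=tuple(a.get("age_regions", ())),
    )
    noise = CohortNoise(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in cfg.get("noise", {}).items()})
    return spec, atrophy, noise


def phantom_config_dict(
    spec: PhantomSpec, atrophy: AtrophySpec, noise: CohortNoise = CohortNoise()
) -> dict:
    """JSON-serializable dict mirroring :func:`load_phantom_config`."""
    return {
        "grid_shape": list(spec.grid_shape),
        "spacing_mm": list(spec.spacing_mm),
        "rng_seed": spec.rng_seed,
        "regions": [
            {"name": r.name, "label": r.label,
             "center_frac": list(r.center_frac), "semi_axes_frac": list(r.semi_axes_frac)}
            for r in spec.region_layout
        ],
        "atrophy": {
            "class_steps": {k: dict(v) for k, v in atrophy.class_steps.items()},
            "m12_increment": {k: dict(v) for k, v in atrophy.m12_increment.items()},
            "converter_increment_class": atrophy.converter_increment_class,
            "fill_region": atrophy.fill_region,
            "min_voxels": atrophy.min_voxels,
            "age_slope": atrophy.age_slope,
            "age_ref": atrophy.age_ref,
            "age_regions": list(atrophy.age_regions),
        },
        "noise": {
            "scale_sigma": noise.scale_sigma,
            "shift_max_voxels": noise.shift_max_voxels,
            "boundary_flip_frac": noise.boundary_flip_frac,
            "age_mean": noise.age_mean,
            "age_sd": noise.age_sd,
            "age_range": list(noise.age_range),
        },
    }


def phantom_fraction_defs() -> "FractionDefs":
    """Volume-fraction region roles for the 14-region phantom: ICV is the whole
    head, CSF shell and lateral ventricles are excluded from the whole-brain
    numerator."""
    from .regionstats import FractionDefs

    spec = default_phantom_spec()
    all_names = tuple(r.name for r in spec.region_layout)
    return FractionDefs(
        icv_regions=all_names,
        excluded_from_wb=("CSF", "Left-Lateral-Ventricle", "Right-Lateral-Ventricle"),
        hippocampus_regions=("Left-Hippocampus", "Right-Hippocampus"),
    )
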