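"""Per-subject markers from a labeled volume.

Implements the three marker families used throughout the package:

* **surface connectivity** — for each region, the percentage of its exposed
  voxel faces shared with every other labeled region.  The discrete surface
  of a region is the set of voxel faces whose 6-neighbor across the face
  carries a different label (out-of-grid neighbors count as background).
  Each row is normalized by its own region's total surface, so the matrix is
  non-symmetric; an entry of zero means the two regions share no faces.
* **centroid landmarks** — the center of mass of each region, computed either
  as the mean of voxel-center coordinates or via the divergence-theorem
  surface integral (both agree exactly for axis-aligned voxel solids).
* **volume fractions** — whole-brain and hippocampal volume divided by the
  intracranial volume.

Marker tables (one row per subject, metadata columns first) are the interface
to the learning pipeline.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .volume import LabeledVolume, load_labeled_volume

__all__ = [
    "GroupingDef",
    "SurfaceFaceSet",
    "ConnectivityMatrix",
    "FractionDefs",
    "VolumeFractions",
    "load_groupings",
    "contact_face_counts",
    "surface_faces",
    "connectivity_matrix",
    "region_volumes",
    "centroid_voxel_mean",
    "centroid_divergence",
    "all_centroids",
    "volume_fractions",
    "features_for_volume",
    "marker_table",
    "delta_table",
    "META_COLUMNS",
    "MARKER_KINDS",
]

logger = logging.getLogger(__name__)

META_COLUMNS = ["id", "diagnosis", "converter", "age_bl", "sex", "timepoint"]

#: marker kinds understood by :func:`marker_table`
MARKER_KINDS = ("surface", "landmarks", "hp_fraction", "wb_fraction")

#: kinds whose longitudinal delta is reported as baseline minus follow-up
#: (positive = volume LOSS)
VOLUME_KINDS = ("hp_fraction", "wb_fraction")


@dataclass(frozen=True)
class GroupingDef:
    """An ordered selection of region names over which markers are computed."""

    name: str
    region_names: tuple[str, ...]

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.region_names)
        if len(set(names)) != len(names):
            raise ValueError(f"grouping {self.name!r} has duplicate region names")
        object.__setattr__(self, "region_names", names)

    def __len__(self) -> int:
        return len(self.region_names)


def load_groupings(source: str | Path) -> dict[str, GroupingDef]:
    """Load grouping definitions from JSON.

    ``source`` is either a path or one of the shipped configs
    (``"paper"`` — the 37/26/16-region all/func/potato groupings;
    ``"phantom"`` — groupings over the 14-region synthetic atlas).
    """
    if source in ("paper", "phantom"):
        text = resources.files("proximark.data").joinpath(f"groupings_{source}.json").read_text()
    else:
        text = Path(source).read_text()
    raw = json.loads(text)
    return {name: GroupingDef(name=name, region_names=tuple(regions)) for name, regions in raw.items()}


# ---------------------------------------------------------------------------
# surface connectivity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurfaceFaceSet:
    """Exposed-face census of one region.

    ``contact_faces`` partitions ``total_faces`` by the neighbor label on the
    other side of each exposed face; key 0 collects background contact,
    including faces on the grid boundary.
    """

    region: str
    total_faces: int
    contact_faces: dict[int, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.contact_faces.values()) or self.total_faces < 0:
            raise ValueError("face counts must be non-negative")
        if sum(self.contact_faces.values()) != self.total_faces:
            raise ValueError("contact faces do not partition the total surface")


@dataclass(frozen=True)
class ConnectivityMatrix:
    """K x K surface-contact percentages in a grouping's region order."""

    regions: tuple[str, ...]
    values: np.ndarray  # (K, K) float, diagonal 0, entries in [0, 100]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.regions),) * 2:
            raise ValueError("values must be K x K for K grouping regions")
        object.__setattr__(self, "values", v)

    def off_diagonal(self) -> np.ndarray:
        """Row-major flattening of the K(K-1) off-diagonal entries."""
        k = len(self.regions)
        mask = ~np.eye(k, dtype=bool)
        return self.values[mask]

    def feature_names(self) -> list[str]:
        return [
            f"{a}->{b}"
            for i, a in enumerate(self.regions)
            for j, b in enumerate(self.regions)
            if i != j
        ]


def contact_face_counts(labels: np.ndarray) -> np.ndarray:
    """Shared-face counts between every pair of labels.

    Returns an ``(m+1, m+1)`` integer matrix ``C`` (m = max label) where
    ``C[a, b]`` is the number of voxel faces with label ``a`` on one side and
    ``b`` on the other.  Faces on the grid boundary are charged to background:
    ``C[a, 0]`` includes them.  ``C`` is symmetric with zero diagonal, and
    ``C[a].sum()`` is the total exposed surface of region ``a`` in faces.
    """
    labels = np.asarray(labels)
    m = int(labels.max(initial=0))
    k = m + 1
    counts = np.zeros((k, k), dtype=np.int64)
    for ax in range(3):
        rolled = np.moveaxis(labels, ax, 0)
        a = rolled[:-1].ravel()
        b = rolled[1:].ravel()
        diff = a != b
        if diff.any():
            flat = np.bincount(a[diff].astype(np.int64) * k + b[diff], minlength=k * k)
            pair = flat.reshape(k, k)
            counts += pair
            counts += pair.T
        for edge in (rolled[0], rolled[-1]):
            nz = edge[edge != 0].astype(np.int64)
            if nz.size:
                boundary = np.bincount(nz, minlength=k)
                counts[:, 0] += boundary
                counts[0, :] += boundary
    return counts


def surface_faces(vol: LabeledVolume, region: int | str) -> SurfaceFaceSet:
    """Exposed-face census of one region against all other labels."""
    lab = vol.resolve(region)
    counts = contact_face_counts(vol.labels)
    row = counts[lab] if lab < counts.shape[0] else np.zeros(1, dtype=np.int64)
    contact = {int(j): int(c) for j, c in enumerate(row) if c > 0}
    name = vol.label_names.get(lab, str(lab))
    return SurfaceFaceSet(region=str(name), total_faces=int(row.sum()), contact_faces=contact)


def connectivity_matrix(vol: LabeledVolume, grouping: GroupingDef) -> ConnectivityMatrix:
    """Non-symmetric surface-contact percentage matrix over a grouping.

    Entry (i, j) is ``100 * (faces region i shares with region j) / (total
    exposed faces of region i)``.  The denominator is the region's full
    surface against *all* labels in the volume, not only those in the
    grouping, so restricting the grouping never changes a region's surface.
    Regions with zero voxels yield a zero row (logged).
    """
    name_to_label = vol.name_to_label
    ids = []
    for name in grouping.region_names:
        if name not in name_to_label:
            raise KeyError(f"grouping {grouping.name!r} region {name!r} not in volume label names")
        ids.append(name_to_label[name])
    counts = contact_face_counts(vol.labels)
    size = counts.shape[0]
    k = len(ids)
    values = np.zeros((k, k), dtype=float)
    for i, li in enumerate(ids):
        total = counts[li].sum() if li < size else 0
        if total == 0:
            logger.warning("region %r has no voxels; connectivity row set to 0", grouping.region_names[i])
            continue
        for j, lj in enumerate(ids):
            if i == j or lj >= size:
                continue
            values[i, j] = 100.0 * counts[li, lj] / total
    return ConnectivityMatrix(regions=grouping.region_names, values=values)


# ---------------------------------------------------------------------------
# volumes and centroids
# ---------------------------------------------------------------------------


def region_volumes(vol: LabeledVolume) -> dict[str, float]:
    """Volume in mm^3 of every named region (0 for regions absent from the array)."""
    counts = np.bincount(vol.labels.ravel(), minlength=max(vol.label_names, default=0) + 1)
    vv = vol.voxel_volume_mm3
    return {
        str(name): float(counts[int(lab)]) * vv if int(lab) < counts.size else 0.0
        for lab, name in vol.label_names.items()
    }


def centroid_voxel_mean(vol: LabeledVolume, region: int | str) -> np.ndarray:
    """Center of mass as the mean of voxel-center coordinates (mm).

    Voxel centers sit at (index + 0.5) * spacing along each axis.
    """
    mask = vol.mask(region)
    if not mask.any():
        raise ValueError(f"region {region!r} is empty")
    idx = np.argwhere(mask)
    spacing = np.asarray(vol.spacing_mm)
    return (idx.mean(axis=0) + 0.5) * spacing


def centroid_divergence(vol: LabeledVolume, region: int | str) -> np.ndarray:
    """Center of mass via a surface integral over exposed voxel faces.

    By the divergence theorem, each coordinate of the centroid of a solid P
    equals ``1/(2V) * sum over boundary faces of the integral of (x.e_d)^2
    times (n.e_d)``, where n is the outward normal.  For a voxel solid, only
    faces normal to axis d contribute to coordinate d and each contributes
    ``sign * (plane position)^2 * face area``.  For axis-aligned voxel solids
    this is exactly the voxel-mean centroid; it is computed here from the
    region's exposed surface alone.
    """
    mask = vol.mask(region)
    if not mask.any():
        raise ValueError(f"region {region!r} is empty")
    spacing = np.asarray(vol.spacing_mm)
    volume = mask.sum() * vol.voxel_volume_mm3
    out = np.zeros(3)
    for d in range(3):
        m = np.moveaxis(mask, d, 0)
        n = m.shape[0]
        # exposed faces with outward normal +e_d / -e_d
        plus = m & ~np.concatenate([m[1:], np.zeros_like(m[:1])], axis=0)
        minus = m & ~np.concatenate([np.zeros_like(m[:1]), m[:-1]], axis=0)
        face_area = np.prod(np.delete(spacing, d))
        planes = np.arange(n + 1) * spacing[d]  # face planes in mm
        plus_counts = plus.reshape(n, -1).sum(axis=1)
        minus_counts = minus.reshape(n, -1).sum(axis=1)
        # +faces of voxel i lie on plane i+1, -faces on plane i
        integral = (plus_counts * planes[1:] ** 2 - minus_counts * planes[:-1] ** 2).sum()
        out[d] = face_area * integral / (2.0 * volume)
    return out


def all_centroids(
    vol: LabeledVolume,
    regions: Sequence[str],
    method: str = "voxel_mean",
) -> np.ndarray:
    """K x 3 centroid coordinates (mm) in the given region order."""
    fn = {"voxel_mean": centroid_voxel_mean, "divergence": centroid_divergence}[method]
    return np.vstack([fn(vol, r) for r in regions])


# ---------------------------------------------------------------------------
# volume fractions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FractionDefs:
    """Which regions enter each volume-fraction marker.

    ``icv_regions`` define the intracranial volume (denominator; includes
    CSF-like regions); ``excluded_from_wb`` are subtracted from the
    whole-brain numerator (CSF and vessels); ``hippocampus_regions`` form the
    hippocampal numerator.
    """

    icv_regions: tuple[str, ...]
    excluded_from_wb: tuple[str, ...]
    hippocampus_regions: tuple[str, ...]


@dataclass(frozen=True)
class VolumeFractions:
    wb_fraction: float
    hp_fraction: float


def volume_fractions(vol: LabeledVolume, defs: FractionDefs) -> VolumeFractions:
    """Whole-brain and hippocampus volume, each divided by intracranial volume."""
    vols = region_volumes(vol)
    missing = [r for r in defs.hippocampus_regions if r not in vols]
    if missing:
        raise KeyError(f"hippocampus regions missing from volume: {missing}")
    icv = sum(vols.get(r, 0.0) for r in defs.icv_regions)
    if icv <= 0:
        raise ValueError("intracranial volume is zero")
    excluded = set(defs.excluded_from_wb)
    wb = sum(v for r, v in vols.items() if r in defs.icv_regions and r not in excluded)
    hp = sum(vols[r] for r in defs.hippocampus_regions)
    return VolumeFractions(wb_fraction=wb / icv, hp_fraction=hp / icv)


# ---------------------------------------------------------------------------
# marker tables
# ---------------------------------------------------------------------------


def features_for_volume(
    vol: LabeledVolume,
    kind: str,
    grouping: GroupingDef | None = None,
    fraction_defs: FractionDefs | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Feature vector (values, names) of one marker kind for one volume."""
    if kind == "surface":
        if grouping is None:
            raise ValueError("surface marker requires a grouping")
        cm = connectivity_matrix(vol, grouping)
        return cm.off_diagonal(), cm.feature_names()
    if kind == "landmarks":
        if grouping is None:
            raise ValueError("landmark marker requires a grouping")
        coords = all_centroids(vol, grouping.region_names)
        names = [f"{r}.{ax}" for r in grouping.region_names for ax in "xyz"]
        return coords.ravel(), names
    if kind in ("hp_fraction", "wb_fraction"):
        if fraction_defs is None:
            raise ValueError(f"{kind} marker requires fraction definitions")
        vf = volume_fractions(vol, fraction_defs)
        value = vf.hp_fraction if kind == "hp_fraction" else vf.wb_fraction
        return np.array([value]), [kind]
    raise ValueError(f"unknown marker kind {kind!r}; expected one of {MARKER_KINDS}")


def marker_table(
    manifest: pd.DataFrame,
    kind: str,
    grouping: GroupingDef | None = None,
    timepoint: str = "bl",
    *,
    fraction_defs: FractionDefs | None = None,
    label_names: Mapping[int, str] | None = None,
    loader: Callable[[pd.Series], LabeledVolume] | None = None,
) -> pd.DataFrame:
    """One marker-feature row per subject at one timepoint.

    ``manifest`` must have the cohort columns (id, diagnosis, converter,
    age_bl, sex, timepoint) plus ``path`` unless a custom ``loader`` is given.
    The returned frame has the metadata columns first, then the marker's
    feature columns; ``attrs['kind']`` records the marker kind.
    """
    if kind not in MARKER_KINDS:
        raise ValueError(f"unknown marker kind {kind!r}")
    if loader is None:
        if label_names is None:
            raise ValueError("label_names required to load volumes from the manifest")

        def loader(row: pd.Series) -> LabeledVolume:
            return load_labeled_volume(row["path"], label_names)

    rows = manifest[manifest["timepoint"] == timepoint]
    if rows.empty:
        raise ValueError(f"no manifest rows at timepoint {timepoint!r}")
    feats, names = [], None
    for _, row in rows.iterrows():
        try:
            vol = loader(row)
        except FileNotFoundError as exc:
            raise FileNotFoundError(f"subject {row['id']}: {exc}") from exc
        values, names = features_for_volume(vol, kind, grouping, fraction_defs)
        feats.append(values)
    meta = rows[META_COLUMNS].reset_index(drop=True)
    table = pd.concat([meta, pd.DataFrame(np.vstack(feats), columns=names)], axis=1)
    table.attrs["kind"] = kind
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def delta_table(bl: pd.DataFrame, m12: pd.DataFrame, kind: str | None = None) -> pd.DataFrame:
    """Longitudinal change of a marker table.

    Features are month-12 minus baseline, except for the volume-fraction
    markers where the sign is flipped (baseline minus month-12) so that a
    positive delta means volume loss, the conventional reading.  Subjects
    present at only one timepoint are dropped with a warning.
    """
    kind = kind or bl.attrs.get("kind")
    cols = feature_columns(bl)
    if cols != feature_columns(m12):
        raise ValueError("baseline and month-12 tables have different feature columns")
    common = bl["id"][bl["id"].isin(m12["id"])]
    dropped = set(bl["id"]) ^ set(m12["id"])
    if dropped:
        warnings.warn(f"subjects present at one timepoint only, excluded: {sorted(dropped)}")
    bl_i = bl.set_index("id").loc[common]
    m12_i = m12.set_index("id").loc[common]
    diff = m12_i[cols].to_numpy(dtype=float) - bl_i[cols].to_numpy(dtype=float)
    if kind in VOLUME_KINDS:
        diff = -diff
    meta = bl_i[[c for c in META_COLUMNS if c != "id"]].reset_index()
    meta["timepoint"] = "delta"
    out = pd.concat([meta, pd.DataFrame(diff, columns=cols)], axis=1)
    out.attrs["kind"] = kind
    return out
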