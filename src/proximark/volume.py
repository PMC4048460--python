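"""Labeled parcellation volumes and NIfTI I/O.

A :class:`LabeledVolume` is the common input of every marker: a 3-D array of
non-negative integer labels (0 = background), per-axis voxel spacing in mm,
and a mapping from label id to region name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = ["LabeledVolume", "load_labeled_volume", "save_labeled_volume"]


@dataclass(frozen=True)
class LabeledVolume:
    """Integer-labeled 3-D volume with voxel spacing and a label-name map.

    Parameters
    ----------
    labels : ndarray of int, 3-D
        Region label at each voxel; 0 is reserved for background.
    spacing_mm : tuple of 3 floats
        Voxel edge lengths along each array axis, in millimetres.
    label_names : mapping int -> str
        Names every positive label present in ``labels``.
    """

    labels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    label_names: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"labels must be 3-D, got ndim={labels.ndim}")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        object.__setattr__(self, "labels", labels)
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing_mm}")
        object.__setattr__(self, "spacing_mm", spacing)
        if labels.size and labels.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        present = set(np.unique(labels).tolist()) - {0}
        missing = present - set(int(k) for k in self.label_names)
        if missing:
            raise ValueError(f"labels present but unnamed: {sorted(missing)}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def name_to_label(self) -> dict[str, int]:
        inv = {str(v): int(k) for k, v in self.label_names.items()}
        if len(inv) != len(self.label_names):
            raise ValueError("label names are not unique")
        return inv

    def resolve(self, region: int | str) -> int:
        """Return the integer label id for a region given by name or id."""
        if isinstance(region, str):
            try:
                return self.name_to_label[region]
            except KeyError:
                raise KeyError(f"unknown region name: {region!r}") from None
        lab = int(region)
        if lab != 0 and lab not in {int(k) for k in self.label_names}:
            raise KeyError(f"unknown label id: {lab}")
        return lab

    def mask(self, region: int | str) -> np.ndarray:
        return self.labels == self.resolve(region)


def save_labeled_volume(vol: LabeledVolume, path: str | Path) -> Path:
    """Write the label array as an integer NIfTI-1 file (affine = spacing)."""
    path = Path(path)
    affine = np.diag(list(vol.spacing_mm) + [1.0])
    img = nib.Nifti1Image(vol.labels.astype(np.int16), affine)
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, str(path))
    return path


def load_labeled_volume(path: str | Path, label_names: Mapping[int, str]) -> LabeledVolume:
    """Read an integer NIfTI-1 label volume.

    NIfTI carries no label table, so ``label_names`` must be supplied (cohorts
    written by this package ship a ``labels.json`` sidecar next to the
    manifest).
    """
    img = nib.load(str(path))
    labels = np.asanyarray(img.dataobj)
    if not np.issubdtype(labels.dtype, np.integer):
        rounded = np.rint(labels)
        if not np.allclose(labels, rounded):
            raise ValueError(f"{path}: voxel values are not integer labels")
        labels = rounded.astype(np.int32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    names = {int(k): str(v) for k, v in label_names.items()}
    return LabeledVolume(labels=np.ascontiguousarray(labels), spacing_mm=spacing, label_names=names)
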