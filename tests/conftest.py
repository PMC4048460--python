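"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from proximark.volume import LabeledVolume

_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def brute_force_contacts(labels: np.ndarray) -> np.ndarray:
    """Triple-loop face enumeration: C[a, b] = faces owned by label a facing b.

    Out-of-grid neighbors count as background (label 0).  Independent oracle
    for the vectorized face counting; O(voxels) Python loop, tiny grids only.
    """
    labels = np.asarray(labels)
    m = int(labels.max(initial=0))
    counts = np.zeros((m + 1, m + 1), dtype=np.int64)
    nx, ny, nz = labels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                lab = labels[x, y, z]
                for dx, dy, dz in _OFFSETS:
                    px, py, pz = x + dx, y + dy, z + dz
                    if 0 <= px < nx and 0 <= py < ny and 0 <= pz < nz:
                        nb = labels[px, py, pz]
                    else:
                        nb = 0
                    if nb != lab:
                        counts[lab, nb] += 1
    return counts


def brute_force_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """O(n^2) pair enumeration: positive>negative pairs + half ties."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).ravel() > 0
    pos, neg = scores[y], scores[~y]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins) / (len(pos) * len(neg))


def make_volume(labels: np.ndarray, spacing=(1.0, 1.0, 1.0), names=None) -> LabeledVolume:
    labels = np.asarray(labels, dtype=np.int16)
    if names is None:
        names = {int(l): f"region-{int(l)}" for l in np.unique(labels) if l != 0}
    return LabeledVolume(labels=labels, spacing_mm=spacing, label_names=names)


def random_connected_solid(rng: np.random.Generator, shape=(12, 12, 12), n_voxels=40) -> np.ndarray:
    """Grow a 6-connected random blob; returns a boolean mask."""
    mask = np.zeros(shape, dtype=bool)
    frontier = [tuple(s // 2 for s in shape)]
    mask[frontier[0]] = True
    cells = [frontier[0]]
    while mask.sum() < n_voxels:
        x, y, z = cells[rng.integers(len(cells))]
        dx, dy, dz = _OFFSETS[rng.integers(6)]
        p = (x + dx, y + dy, z + dz)
        if all(0 <= c < s for c, s in zip(p, shape)) and not mask[p]:
            mask[p] = True
            cells.append(p)
    return mask


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
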