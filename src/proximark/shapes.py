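"""Generalized Procrustes alignment of region-centroid landmark sets.

Each subject contributes an ordered set of K region centroids.  Alignment
removes translation (centering), size (centroid size, the root sum of squares
of the centered coordinates) and orientation (optimal proper rotation, via SVD
of the cross-covariance with the usual determinant sign fix — reflections are
never allowed, anatomical landmark sets must not be mirrored).  GPA iterates
alignment of all sets to their evolving mean shape, starting from the mean,
until the mean stabilizes.  After convergence the arbitrary global rotation is
fixed by rotating the mean to its principal axes with a deterministic sign
convention, so feature vectors are reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "LandmarkSet",
    "GPAResult",
    "center_and_scale",
    "optimal_rotation",
    "gpa",
    "align_to_mean",
    "save_landmarks_tsv",
    "load_landmarks_tsv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LandmarkSet:
    """Ordered K x 3 landmark coordinates (mm) with region names."""

    regions: tuple[str, ...]
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (len(self.regions), 3):
            raise ValueError(f"coords must be ({len(self.regions)}, 3), got {coords.shape}")
        if len(self.regions) < 3:
            raise ValueError("need at least 3 landmarks")
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("duplicate region names in landmark set")
        if not np.isfinite(coords).all():
            raise ValueError("landmark coordinates must be finite")
        object.__setattr__(self, "coords", coords)

    def flatten(self) -> np.ndarray:
        """Row-major feature vector (x1, y1, z1, x2, ...) of length 3K."""
        return self.coords.ravel().copy()


@dataclass
class GPAResult:
    mean_shape: LandmarkSet
    aligned: list[LandmarkSet]
    translations: np.ndarray      # (n, 3) original centroids
    scales: np.ndarray            # (n,) original centroid sizes
    rotations: np.ndarray         # (n, 3, 3) rotations applied to normalized sets
    n_iter: int
    converged: bool
    objective_history: list[float]

    def feature_matrix(self) -> np.ndarray:
        return np.vstack([s.flatten() for s in self.aligned])


def center_and_scale(s: LandmarkSet) -> tuple[LandmarkSet, np.ndarray, float]:
    """Center the set at the origin and scale it to unit centroid size.

    Returns (normalized set, original centroid, original centroid size).
    """
    centroid = s.coords.mean(axis=0)
    centered = s.coords - centroid
    size = float(np.sqrt((centered ** 2).sum()))
    if size <= 0 or not np.isfinite(size):
        raise ValueError("landmark set has zero size (all points identical)")
    return LandmarkSet(s.regions, centered / size), centroid, size


def optimal_rotation(A: np.ndarray | LandmarkSet, B: np.ndarray | LandmarkSet) -> np.ndarray:
    """Proper rotation R minimizing ||A R - B||_F over rotations (Kabsch).

    Both inputs are centered K x 3 configurations with matching landmark
    order.  The SVD sign correction guarantees det(R) = +1; for rank-deficient
    configurations the correction acts on the smallest singular value and a
    warning is logged.
    """
    if isinstance(A, LandmarkSet):
        if isinstance(B, LandmarkSet) and A.regions != B.regions:
            raise ValueError("landmark sets have different region orders")
        A = A.coords
    if isinstance(B, LandmarkSet):
        B = B.coords
    H = np.asarray(A).T @ np.asarray(B)
    U, S, Vt = np.linalg.svd(H)
    d = float(np.sign(np.linalg.det(U @ Vt)) or 1.0)
    if S[-1] <= S[0] * 1e-12:
        logger.warning("rank-deficient landmark configuration; rotation fixed by sign correction")
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    return R


def _align_one(coords_norm: np.ndarray, mean: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Rotate and rescale one unit-size configuration onto the mean shape."""
    R = optimal_rotation(coords_norm, mean)
    rotated = coords_norm @ R
    beta = float((rotated * mean).sum())  # optimal scale for a unit-size config
    return rotated * beta, R, beta


def gpa(
    sets: Sequence[LandmarkSet],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> GPAResult:
    """Full similarity generalized Procrustes analysis.

    All sets are centered and scaled to unit size; the (renormalized) mean of
    the normalized sets is the starting shape.  Each iteration aligns every
    set to the current mean by rotation and scale, recomputes the mean and
    renormalizes it, until the Frobenius change of the mean falls below
    ``tol`` or ``max_iter`` is reached (then ``converged`` is False).
    """
    if len(sets) < 2:
        raise ValueError("GPA needs at least 2 landmark sets")
    regions = sets[0].regions
    if any(s.regions != regions for s in sets):
        raise ValueError("all landmark sets must share the same region order")
    n = len(sets)
    normalized = np.empty((n, len(regions), 3))
    translations = np.empty((n, 3))
    sizes = np.empty(n)
    for i, s in enumerate(sets):
        ns, translations[i], sizes[i] = center_and_scale(s)
        normalized[i] = ns.coords

    mean = normalized.mean(axis=0)
    mean /= np.sqrt((mean ** 2).sum())
    aligned = normalized.copy()
    rotations = np.tile(np.eye(3), (n, 1, 1))
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            aligned[i], rotations[i], _ = _align_one(normalized[i], mean)
        history.append(float(((aligned - mean) ** 2).sum()))
        new_mean = aligned.mean(axis=0)
        new_mean /= np.sqrt((new_mean ** 2).sum())
        change = float(np.sqrt(((new_mean - mean) ** 2).sum()))
        mean = new_mean
        if change < tol:
            converged = True
            break

    # fix the rotation gauge: principal axes of the mean, deterministic signs
    gauge = _principal_axis_gauge(mean)
    mean = mean @ gauge
    aligned = aligned @ gauge
    rotations = rotations @ gauge
    return GPAResult(
        mean_shape=LandmarkSet(regions, mean),
        aligned=[LandmarkSet(regions, aligned[i]) for i in range(n)],
        translations=translations,
        scales=sizes,
        rotations=rotations,
        n_iter=it,
        converged=converged,
        objective_history=history,
    )


def _principal_axis_gauge(mean: np.ndarray) -> np.ndarray:
    """Rotation taking the mean shape to its principal axes.

    Eigenvectors of the 3 x 3 coordinate covariance, sorted by decreasing
    eigenvalue; each axis is signed so the coordinate of largest magnitude
    along it is positive, and a proper rotation is enforced by flipping the
    last axis if necessary.
    """
    cov = mean.T @ mean
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order]
    proj = mean @ axes
    for d in range(3):
        col = proj[:, d]
        if col[np.argmax(np.abs(col))] < 0:
            axes[:, d] = -axes[:, d]
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    return axes


def save_landmarks_tsv(s: LandmarkSet, path) -> None:
    """Write a landmark set as TSV (region, x, y, z), e.g. a GPA mean shape
    stored alongside experiment outputs for audit."""
    lines = ["region\tx\ty\tz"]
    lines += [f"{r}\t{x:.17g}\t{y:.17g}\t{z:.17g}" for r, (x, y, z) in zip(s.regions, s.coords)]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_landmarks_tsv(path) -> LandmarkSet:
    with open(path) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh][1:]
    return LandmarkSet(
        tuple(r[0] for r in rows), np.array([[float(v) for v in r[1:4]] for r in rows])
    )


def align_to_mean(s: LandmarkSet, mean: LandmarkSet) -> LandmarkSet:
    """Similarity-align one landmark set to a fixed mean shape.

    Used for held-out subjects in cross-validation: the mean comes from the
    training fold's GPA and is not refit.  ``mean`` must be centered and of
    unit size (as produced by :func:`gpa`).
    """
    if s.regions != mean.regions:
        raise ValueError("landmark sets have different region orders")
    ns, _, _ = center_and_scale(s)
    aligned, _, _ = _align_one(ns.coords, mean.coords)
    return LandmarkSet(s.regions, aligned)
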