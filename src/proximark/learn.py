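"""Dimensionality reduction, classification and evaluation.

The classification pipeline is: optional covariate residualization of the
feature columns (gated per covariate by a Pearson-correlation test on the
training rows), optional per-fold Procrustes alignment for landmark features,
PLS dimensionality reduction to 10 latent components (NIPALS, scalar class
code as the response), and a two-class linear discriminant on the PLS scores.
Evaluation is leave-one-of-each-class-out cross-validation: every fold holds
out one subject from each contrast class, and each subject's out-of-fold
decision score feeds a Mann-Whitney AUC and a Wilcoxon rank-sum test.

Everything here is deterministic given the fold shuffling seed; all model
fitting uses training rows only.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .shapes import LandmarkSet, align_to_mean, gpa

__all__ = [
    "Residualizer",
    "PLSModel",
    "pls_fit",
    "LDAModel",
    "lda_fit",
    "auc",
    "ranksum_test",
    "PipelineConfig",
    "FoldModel",
    "CVResult",
    "cv_leave_one_per_class",
]

_EPS = np.finfo(float).eps


# ---------------------------------------------------------------------------
# covariate residualization
# ---------------------------------------------------------------------------


@dataclass
class Residualizer:
    """Per-feature linear adjustment for covariates, gated by correlation.

    For each feature column, each covariate is tested for Pearson correlation
    on the *training* rows; if any covariate is significant at ``gate_alpha``
    the column is replaced by the residuals of an ordinary least-squares fit
    (intercept + the significant covariates), fit on training rows and applied
    to all rows.  Constant covariates are skipped with a warning.
    """

    gate_alpha: float
    kept_covariates: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    gates: np.ndarray = field(default_factory=lambda: np.empty((0, 0), dtype=bool))
    patterns: list[tuple[tuple[int, ...], np.ndarray, np.ndarray]] = field(default_factory=list)
    # patterns: (covariate indices, feature column indices, OLS coefficients)

    @classmethod
    def fit(cls, X: np.ndarray, covariates: np.ndarray, gate_alpha: float = 0.05) -> "Residualizer":
        X = np.asarray(X, dtype=float)
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != X.shape[0]:
            C = C.T
        n, p = X.shape
        keep = []
        for k in range(C.shape[1]):
            if np.std(C[:, k]) == 0:
                warnings.warn(f"covariate {k} is constant on training rows; skipped")
            else:
                keep.append(k)
        model = cls(gate_alpha=gate_alpha, kept_covariates=np.array(keep, dtype=int))
        if not keep or gate_alpha <= 0 or n < 3:
            model.gates = np.zeros((p, len(keep)), dtype=bool)
            return model
        Ck = C[:, keep]
        # vectorized Pearson r of every feature column against every covariate
        Xc = X - X.mean(axis=0)
        Cc = Ck - Ck.mean(axis=0)
        xs = np.sqrt((Xc ** 2).sum(axis=0))
        cs = np.sqrt((Cc ** 2).sum(axis=0))
        denom = np.outer(xs, cs)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, (Xc.T @ Cc) / np.where(denom > 0, denom, 1.0), 0.0)
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, _EPS))
        pvals = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        gates = pvals < gate_alpha
        model.gates = gates
        # group feature columns by identical gate pattern and fit one OLS each
        if gates.any():
            patterns = {}
            for j in np.flatnonzero(gates.any(axis=1)):
                patterns.setdefault(tuple(np.flatnonzero(gates[j])), []).append(j)
            for cov_idx, cols in patterns.items():
                design = np.column_stack([np.ones(n), Ck[:, list(cov_idx)]])
                beta, *_ = np.linalg.lstsq(design, X[:, cols], rcond=None)
                model.patterns.append((cov_idx, np.array(cols, dtype=int), beta))
        return model

    def transform(self, X: np.ndarray, covariates: np.ndarray) -> np.ndarray:
        X = np.array(X, dtype=float, copy=True)
        if not self.patterns:
            return X
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != X.shape[0]:
            C = C.T
        Ck = C[:, self.kept_covariates]
        for cov_idx, cols, beta in self.patterns:
            design = np.column_stack([np.ones(X.shape[0]), Ck[:, list(cov_idx)]])
            X[:, cols] -= design @ beta
        return X


# ---------------------------------------------------------------------------
# partial least squares (NIPALS, single response)
# ---------------------------------------------------------------------------


@dataclass
class PLSModel:
    """Sequential PLS decomposition of X against a scalar class code.

    ``W`` holds the unit weight vectors (the first maximizes the covariance of
    the X-score with y), ``P`` the X-loadings used for deflation, ``q`` the
    per-component regressions of y on the scores.  ``rotations = W (P'W)^-1``
    maps centered X directly to scores, so held-out rows are projected without
    re-running the deflation.
    """

    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray           # (p, A)
    P: np.ndarray           # (p, A)
    q: np.ndarray           # (A,)
    rotations: np.ndarray   # (p, A)
    coef: np.ndarray        # (p,)

    @property
    def n_components(self) -> int:
        return self.W.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.x_mean.size:
            raise ValueError(f"expected {self.x_mean.size} features, got {X.shape[1]}")
        return (X - self.x_mean) @ self.rotations

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean) @ self.coef + self.y_mean


def pls_fit(X: np.ndarray, y: np.ndarray, n_components: int = 10) -> PLSModel:
    """NIPALS PLS with X-deflation and a scalar response (class code +-1).

    Components are extracted sequentially: the weight vector is the normalized
    covariance of the (deflated) columns with y, the score is the projection
    of X onto it, and X is deflated by the score's loading.  The requested
    number of components is truncated (with a warning) to what the data can
    support, min(n - 1, p) and the effective rank.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise ValueError("PLS needs at least 3 training rows")
    limit = min(n_components, n - 1, p)
    if limit < n_components:
        warnings.warn(f"n_components truncated from {n_components} to {limit}")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yc = y - y_mean
    scale = max(float(np.abs(Xd).max()), 1.0)
    W, P, q = [], [], []
    for _ in range(limit):
        w = Xd.T @ yc
        nw = float(np.linalg.norm(w))
        if nw <= 1e-12 * scale * max(float(np.linalg.norm(yc)), 1.0):
            warnings.warn("PLS stopped early: no remaining X-y covariance")
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= (1e-12 * scale) ** 2:
            warnings.warn("PLS stopped early: degenerate score")
            break
        load = Xd.T @ t / tt
        q.append(float(yc @ t / tt))
        W.append(w)
        P.append(load)
        Xd = Xd - np.outer(t, load)
    if not W:
        raise ValueError("no PLS components could be extracted (X has no covariance with y)")
    W = np.column_stack(W)
    P = np.column_stack(P)
    q = np.asarray(q)
    rotations = W @ np.linalg.inv(P.T @ W)
    return PLSModel(x_mean=x_mean, y_mean=y_mean, W=W, P=P, q=q,
                    rotations=rotations, coef=rotations @ q)


# ---------------------------------------------------------------------------
# linear discriminant analysis (two classes, pooled covariance)
# ---------------------------------------------------------------------------


@dataclass
class LDAModel:
    """Fisher discriminant direction with midpoint offset.

    Decision value ``w'x - w'(mu+ + mu-)/2``; larger values vote for the class
    coded +1.
    """

    w: np.ndarray
    offset: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.w - self.offset


def lda_fit(scores: np.ndarray, y: np.ndarray, ridge: float = 1e-6) -> LDAModel:
    """Closed-form two-class LDA: w proportional to S_pooled^{-1} (mu+ - mu-).

    If the pooled within-class covariance is singular (or numerically so), a
    ridge of ``ridge * trace(S)/d`` is added to the diagonal; if it is still
    singular an error is raised.
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(y).ravel()
    pos, neg = X[y > 0], X[y <= 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("LDA needs at least 2 training rows per class")
    mu_p, mu_n = pos.mean(axis=0), neg.mean(axis=0)
    d = X.shape[1]
    Sw = ((pos - mu_p).T @ (pos - mu_p) + (neg - mu_n).T @ (neg - mu_n)) / (len(pos) + len(neg) - 2)
    if np.linalg.cond(Sw) > 1e12 or not np.isfinite(np.linalg.cond(Sw)):
        Sw = Sw + ridge * (np.trace(Sw) / d) * np.eye(d)
    try:
        w = np.linalg.solve(Sw, mu_p - mu_n)
    except np.linalg.LinAlgError as exc:
        raise ValueError("pooled covariance is singular even after ridge") from exc
    if not np.isfinite(w).all() or not w.any():
        raise ValueError("LDA direction is degenerate")
    return LDAModel(w=w, offset=float(w @ (mu_p + mu_n) / 2.0))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Area under the ROC curve, Mann-Whitney formulation.

    ``(number of positive > negative score pairs + 0.5 * ties) / (n+ n-)``,
    computed with midranks.  ``y > 0`` marks the positive class.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).ravel() > 0
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def ranksum_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Exact enumeration when the combined sample is small (n1 + n2 <= 12) and
    tie-free; otherwise the normal approximation with midranks, tie-corrected
    variance and continuity correction.  Returns (rank-sum statistic of the
    first sample, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank-sum test needs two non-empty samples")
    combined = np.concatenate([a, b])
    ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    w = float(stats.rankdata(combined)[: a.size].sum())
    return w, float(res.pvalue)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """Per-fold pipeline settings.

    ``landmark_regions`` switches on per-fold generalized Procrustes
    alignment: feature rows are interpreted as K x 3 centroid sets, the mean
    shape is fit on the training fold only, and held-out rows are aligned to
    that mean without refitting.
    """

    n_components: int = 10
    gate_alpha: float = 0.05
    ridge: float = 1e-6
    landmark_regions: tuple[str, ...] | None = None
    gpa_tol: float = 1e-10
    gpa_max_iter: int = 100


@dataclass
class FoldModel:
    """Everything fit on one training fold, applicable to held-out rows."""

    residualizer: Residualizer | None
    gpa_mean: LandmarkSet | None
    pls: PLSModel
    lda: LDAModel

    def decision(self, X: np.ndarray, covariates: np.ndarray | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.residualizer is not None:
            X = self.residualizer.transform(X, covariates)
        if self.gpa_mean is not None:
            X = np.vstack([
                align_to_mean(LandmarkSet(self.gpa_mean.regions, row.reshape(-1, 3)),
                              self.gpa_mean).flatten()
                for row in X
            ])
        return self.lda.decision(self.pls.transform(X))

    def hash(self) -> str:
        h = hashlib.sha256()
        parts: list[np.ndarray] = []
        if self.residualizer is not None:
            parts.append(self.residualizer.gates.astype(np.uint8))
            for _, cols, beta in self.residualizer.patterns:
                parts.extend([cols.astype(np.int64), beta])
        if self.gpa_mean is not None:
            parts.append(self.gpa_mean.coords)
        parts.extend([self.pls.x_mean, np.atleast_1d(self.pls.y_mean),
                      self.pls.W, self.pls.P, self.pls.q,
                      self.lda.w, np.atleast_1d(self.lda.offset)])
        for arr in parts:
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()


@dataclass
class CVResult:
    """Out-of-fold decision scores of a leave-one-of-each-class-out run."""

    indices: np.ndarray         # row indices of the contrast subset
    scores: np.ndarray          # one out-of-fold score per subject
    y: np.ndarray               # +1 for the second contrast class
    contrast: tuple[str, str]
    fold_holdouts: list[tuple[int, int]]
    fold_hashes: list[str]

    @property
    def auc(self) -> float:
        return auc(self.scores, self.y)

    def ranksum(self) -> tuple[float, float]:
        return ranksum_test(self.scores[self.y < 0], self.scores[self.y > 0])


def _fit_fold(
    Xtr: np.ndarray,
    ytr: np.ndarray,
    covtr: np.ndarray | None,
    config: PipelineConfig,
) -> FoldModel:
    residualizer = None
    if covtr is not None and covtr.size:
        residualizer = Residualizer.fit(Xtr, covtr, config.gate_alpha)
        Xtr = residualizer.transform(Xtr, covtr)
    gpa_mean = None
    if config.landmark_regions is not None:
        regions = tuple(config.landmark_regions)
        sets = [LandmarkSet(regions, row.reshape(-1, 3)) for row in Xtr]
        result = gpa(sets, tol=config.gpa_tol, max_iter=config.gpa_max_iter)
        gpa_mean = result.mean_shape
        Xtr = result.feature_matrix()
    pls = pls_fit(Xtr, ytr, config.n_components)
    lda = lda_fit(pls.transform(Xtr), ytr, config.ridge)
    return FoldModel(residualizer=residualizer, gpa_mean=gpa_mean, pls=pls, lda=lda)


def cv_leave_one_per_class(
    X: np.ndarray,
    class_labels: Sequence[str],
    contrast: tuple[str, str],
    *,
    covariates: np.ndarray | None = None,
    config: PipelineConfig = PipelineConfig(),
    seed: int = 0,
) -> CVResult:
    """Leave-one-of-each-class-out cross-validation of the full pipeline.

    Both classes are shuffled with ``seed``; fold t (t = 0..n_larger-1) holds
    out subject t of the larger class and subject t mod n_smaller of the
    smaller one, so smaller-class subjects are reused as holdouts but each
    subject's recorded score comes from the first fold holding it out.  Every
    model component is fit on the fold's training rows only.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(class_labels)
    neg, pos = contrast
    idx_neg = np.flatnonzero(labels == neg)
    idx_pos = np.flatnonzero(labels == pos)
    if len(idx_neg) < 3 or len(idx_pos) < 3:
        raise ValueError(
            f"contrast {contrast} needs >=3 subjects per class, "
            f"got {len(idx_neg)} vs {len(idx_pos)}"
        )
    rng = np.random.default_rng(seed)
    idx_neg = rng.permutation(idx_neg)
    idx_pos = rng.permutation(idx_pos)
    if len(idx_pos) >= len(idx_neg):
        larger, smaller = idx_pos, idx_neg
    else:
        larger, smaller = idx_neg, idx_pos
    subset = np.concatenate([idx_neg, idx_pos])
    y = np.concatenate([-np.ones(len(idx_neg)), np.ones(len(idx_pos))])
    y_by_row = dict(zip(subset.tolist(), y.tolist()))

    scores: dict[int, float] = {}
    fold_holdouts: list[tuple[int, int]] = []
    fold_hashes: list[str] = []
    for t in range(len(larger)):
        hold = (int(larger[t]), int(smaller[t % len(smaller)]))
        train = np.array([i for i in subset if i not in hold])
        ytr = np.array([y_by_row[i] for i in train])
        covtr = covariates[train] if covariates is not None else None
        model = _fit_fold(X[train], ytr, covtr, config)
        covte = covariates[list(hold)] if covariates is not None else None
        s = model.decision(X[list(hold)], covte)
        for i, si in zip(hold, s):
            scores.setdefault(i, float(si))
        fold_holdouts.append(hold)
        fold_hashes.append(model.hash())
    return CVResult(
        indices=subset,
        scores=np.array([scores[i] for i in subset]),
        y=y,
        contrast=contrast,
        fold_holdouts=fold_holdouts,
        fold_hashes=fold_hashes,
    )
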