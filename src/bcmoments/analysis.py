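"""Downstream analyses of moment feature vectors.

Three consumers of the 49-D descriptors: a cross-validated
classification harness (SVM or random forest over standardized
features), a kernel-PCA embedding whose first three principal
components form a 3-D "structure universe", and Gaussian-kernel
mean-shift clustering whose cluster count serves as a proxy for
structural variation within a group of domains.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


@dataclasses.dataclass(frozen=True)
class EmbeddingResult:
    """First three kernel principal components of the feature cloud."""

    coords: np.ndarray  # (n_samples, 3)
    kernel_width: float
    eigenvalues: np.ndarray  # non-increasing


@dataclasses.dataclass(frozen=True)
class ClusterResult:
    labels: np.ndarray
    n_clusters: int
    modes: np.ndarray
    bandwidth: float


def _make_classifier(classifier: str, seed: int):
    if classifier == "svm":
        grid = {"clf__C": [1.0, 10.0, 100.0], "clf__gamma": ["scale", 0.01, 0.1]}
        pipe = Pipeline([("scale", StandardScaler()), ("clf", SVC(kernel="rbf"))])
        inner = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
        return GridSearchCV(pipe, grid, cv=inner, n_jobs=1)
    if classifier == "rf":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", RandomForestClassifier(n_estimators=200, random_state=seed)),
            ]
        )
    raise ValueError(f"classifier must be 'svm' or 'rf', got {classifier!r}")


def cross_validate(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 3,
    classifier: str = "svm",
    seed: int = 0,
) -> float:
    """Mean k-fold cross-validated accuracy (fraction correctly classified).

    Standardization (and, for the SVM, the hyperparameter grid search)
    is fit inside each training fold only.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs at least k={k} members (smallest has {counts.min()})")
    model = _make_classifier(classifier, seed)
    outer = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = cross_val_score(model, features, labels, cv=outer, scoring="accuracy", n_jobs=1)
    return float(scores.mean())


def _gaussian_kernel_matrix(x: np.ndarray, width: float) -> np.ndarray:
    d2 = cdist(x, x, metric="sqeuclidean")
    return np.exp(-d2 / width)


def kpca_embed(
    features: np.ndarray,
    kernel_width: float | str = "auto",
    n_components: int = 3,
) -> EmbeddingResult:
    """Gaussian-kernel PCA; returns the first ``n_components`` components.

    The kernel matrix K_ij = exp(-|x_i - x_j|^2 / w) is double-centered
    and its top eigenvectors v_c (normalized so the feature-space
    components have unit norm, i.e. scaled by 1/sqrt(eigenvalue)) give
    the embedding coordinates K_centered @ (v_c / sqrt(l_c)) =
    v_c * sqrt(l_c).  ``"auto"`` sets w to the median pairwise squared
    distance.  Component signs are fixed by making the first
    nonzero coordinate of each eigenvector positive.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValueError("features must be 2-D")
    n = x.shape[0]
    if n < n_components + 1:
        raise ValueError(f"need at least {n_components + 1} samples, got {n}")
    if kernel_width == "auto":
        d2 = pdist(x, metric="sqeuclidean")
        width = float(np.median(d2))
        if width == 0.0:
            raise ValueError("degenerate input: all samples identical (zero median distance)")
    else:
        width = float(kernel_width)
        if width <= 0:
            raise ValueError("kernel_width must be positive")
    k = _gaussian_kernel_matrix(x, width)
    one = np.full((n, n), 1.0 / n)
    kc = k - one @ k - k @ one + one @ k @ one
    eigval, eigvec = np.linalg.eigh(kc)
    order = np.argsort(eigval)[::-1][:n_components]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    if eigval[n_components - 1] <= 1e-12:
        raise ValueError("kernel matrix is rank deficient: fewer distinct samples than components")
    for c in range(n_components):
        col = eigvec[:, c]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            eigvec[:, c] = -col
    coords = eigvec * np.sqrt(eigval)
    return EmbeddingResult(coords=coords, kernel_width=width, eigenvalues=eigval)


def mean_shift_cluster(
    features: np.ndarray,
    bandwidth: float | str = "auto",
    max_iter: int = 300,
    tol_factor: float = 1e-5,
) -> ClusterResult:
    """Gaussian-kernel mean-shift mode seeking.

    Every point ascends to a density mode by repeated kernel-weighted
    averaging; modes closer than bandwidth/2 are merged and each point
    is labeled by its mode.  ``"auto"`` bandwidth is the 0.3 quantile of
    pairwise distances.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("features must be a non-empty 2-D array")
    n = x.shape[0]
    if bandwidth == "auto":
        if n == 1:
            h = 1.0
        else:
            d = pdist(x)
            h = float(np.quantile(d, 0.3))
            if h == 0.0:
                h = float(d.max()) or 1.0
    else:
        h = float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")

    points = x.copy()
    tol = tol_factor * h
    active = np.ones(n, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        d2 = cdist(points[active], x, metric="sqeuclidean")
        w = np.exp(-d2 / (2.0 * h * h))
        new = (w @ x) / w.sum(axis=1, keepdims=True)
        shift = np.linalg.norm(new - points[active], axis=1)
        points[active] = new
        still = np.zeros(n, dtype=bool)
        still[np.flatnonzero(active)[shift >= tol]] = True
        active = still

    # merge modes closer than h/2, in point order
    modes: list[np.ndarray] = []
    labels = np.empty(n, dtype=int)
    for i, pt in enumerate(points):
        for m, mode in enumerate(modes):
            if np.linalg.norm(pt - mode) < h / 2.0:
                labels[i] = m
                break
        else:
            labels[i] = len(modes)
            modes.append(pt)
    return ClusterResult(
        labels=labels, n_clusters=len(modes), modes=np.array(modes), bandwidth=h
    )
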