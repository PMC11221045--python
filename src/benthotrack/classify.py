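"""Benthoscape classification: PCA over environmental layers, unsupervised
clustering, and ground-truth accuracy assessment.

The habitat-quantification chain reduces a stack of co-registered
continuous layers (bathymetry and backscatter derivatives) to principal
components retaining at least 95% of the variance, clusters the per-cell
component vectors into substrate classes, and scores the resulting map
against ground-truth points by overall accuracy, Cohen's kappa, and
per-class user's accuracy.

The clustering step is plain k-means (k-means++ start, Lloyd iterations,
empty clusters re-seeded from the farthest point) — the split/merge
heuristics of full ISODATA and object-based image segmentation are out
of scope. PCA is performed on the correlation matrix because bathymetry
and backscatter live on incommensurate scales. Cluster labels are
arbitrary; ``majority_relabel`` maps them to named classes by majority
vote against ground-truth points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import BenthoscapeRaster


@dataclass
class PCAResult:
    components: np.ndarray  # (n_retained, n_layers) loadings
    scores: np.ndarray  # (n_cells, n_retained) cell scores
    explained: np.ndarray  # all k explained-variance fractions
    n_retained: int


def pca_retain(stack, variance_target: float = 0.95) -> PCAResult:
    """Correlation-matrix PCA keeping >= ``variance_target`` variance.

    ``stack`` is (k, n_rows, n_cols) or (k, n_cells); layers are
    standardized to zero mean / unit variance over finite cells, the
    correlation matrix is eigendecomposed, and the smallest prefix of
    components whose cumulative explained variance reaches the target is
    retained.
    """
    arr = np.asarray(stack, dtype=float)
    if arr.ndim == 3:
        arr = arr.reshape(arr.shape[0], -1)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 layers on a shared grid")
    mask = np.all(np.isfinite(arr), axis=0)
    if mask.sum() < 10:
        raise ValueError("need at least 10 unmasked cells")
    Z = arr[:, mask]
    sd = Z.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.argmax(sd == 0))
        raise ValueError(f"layer {bad} is constant over unmasked cells")
    Z = (Z - Z.mean(axis=1, keepdims=True)) / sd[:, None]
    corr = (Z @ Z.T) / Z.shape[1]
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    explained = np.maximum(evals, 0.0) / arr.shape[0]
    n_ret = int(np.searchsorted(np.cumsum(explained), variance_target) + 1)
    n_ret = min(n_ret, arr.shape[0])
    scores = Z.T @ evecs[:, :n_ret]
    return PCAResult(
        components=evecs[:, :n_ret].T,
        scores=scores,
        explained=explained,
        n_retained=n_ret,
    )


@dataclass
class ClusterResult:
    labels: np.ndarray
    centroids: np.ndarray
    inertia_path: list[float]  # within-cluster SSQ after each Lloyd update
    n_iter: int


def iso_cluster(
    points, k: int, max_iter: int = 100, seed: int | np.random.Generator = 0
) -> ClusterResult:
    """K-means clustering of per-cell component vectors.

    K-means++ initialization, Lloyd iterations to an assignment fixpoint
    or ``max_iter``; a cluster that empties is re-seeded from the point
    farthest from its centroid. Deterministic given the seed.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    n_distinct = np.unique(X, axis=0).shape[0]
    if n_distinct < k:
        raise ValueError(f"only {n_distinct} distinct vectors for k = {k} clusters")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # k-means++ seeding
    centroids = np.empty((k, X.shape[1]))
    centroids[0] = X[rng.integers(len(X))]
    d2 = np.sum((X - centroids[0]) ** 2, axis=1)
    for j in range(1, k):
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(len(X), 1.0 / len(X))
        centroids[j] = X[rng.choice(len(X), p=probs)]
        d2 = np.minimum(d2, np.sum((X - centroids[j]) ** 2, axis=1))

    labels = np.full(len(X), -1)
    inertia_path: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        dist = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = np.argmin(dist, axis=1)
        for j in range(k):
            sel = new_labels == j
            if sel.any():
                centroids[j] = X[sel].mean(axis=0)
            else:  # empty cluster: re-seed from the farthest point
                far = int(np.argmax(dist.min(axis=1)))
                centroids[j] = X[far]
                new_labels[far] = j
        inertia = float(((X - centroids[new_labels]) ** 2).sum())
        inertia_path.append(inertia)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    return ClusterResult(labels=labels, centroids=centroids, inertia_path=inertia_path, n_iter=n_iter)


def cluster_raster(
    pca: PCAResult, template: BenthoscapeRaster | tuple[int, int], k: int,
    max_iter: int = 100, seed: int = 0,
):
    """Cluster PCA scores and lay labels back onto the raster grid."""
    res = iso_cluster(pca.scores, k, max_iter=max_iter, seed=seed)
    shape = (
        (template.n_rows, template.n_cols)
        if isinstance(template, BenthoscapeRaster)
        else template
    )
    grid = res.labels.reshape(shape)
    return grid, res


@dataclass
class AccuracyReport:
    confusion: np.ndarray  # rows = predicted, columns = true
    classes: list
    overall_accuracy: float
    kappa: float
    users_accuracy: dict  # class -> accuracy or None when never predicted


def confusion_matrix(predicted, true, classes=None) -> tuple[np.ndarray, list]:
    pred = np.asarray(predicted)
    tru = np.asarray(true)
    if pred.size == 0 or pred.size != tru.size:
        raise ValueError("need matching, non-empty predicted/true label arrays")
    if classes is None:
        classes = sorted(set(pred.tolist()) | set(tru.tolist()))
    lut = {c: i for i, c in enumerate(classes)}
    m = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for p, t in zip(pred, tru):
        m[lut[p], lut[t]] += 1
    return m, list(classes)


def accuracy_assessment(predicted, true, classes=None) -> AccuracyReport:
    """Overall accuracy, Cohen's kappa, and per-class user's accuracy.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with the expected agreement
    ``p_e`` from the row/column marginals. User's accuracy of a class is
    correct predictions over total predictions of that class; classes
    never predicted have it undefined (reported as ``None``).
    """
    m, cls = confusion_matrix(predicted, true, classes)
    return assessment_from_matrix(m, cls)


def assessment_from_matrix(m: np.ndarray, classes=None) -> AccuracyReport:
    m = np.asarray(m, dtype=np.int64)
    total = m.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    if np.any(m < 0):
        raise ValueError("confusion matrix counts must be non-negative")
    classes = list(classes) if classes is not None else list(range(m.shape[0]))
    p_o = np.trace(m) / total
    row = m.sum(axis=1) / total
    col = m.sum(axis=0) / total
    p_e = float(row @ col)
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    users = {}
    for i, c in enumerate(classes):
        denom = m[i].sum()
        users[c] = None if denom == 0 else float(m[i, i] / denom)
    return AccuracyReport(
        confusion=m,
        classes=classes,
        overall_accuracy=float(p_o),
        kappa=float(kappa),
        users_accuracy=users,
    )


def majority_relabel(labels: np.ndarray, gt_labels: np.ndarray, gt_clusters: np.ndarray):
    """Map arbitrary cluster ids to named classes by ground-truth majority vote.

    Clusters with no ground-truth points keep their original id offset
    out of the named range.
    """
    mapping = {}
    for cl in np.unique(gt_clusters):
        vals, cnt = np.unique(gt_labels[gt_clusters == cl], return_counts=True)
        mapping[int(cl)] = int(vals[np.argmax(cnt)])
    out = np.array([mapping.get(int(v), int(v) + 1000) for v in np.ravel(labels)])
    return out.reshape(np.shape(labels)), mapping
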