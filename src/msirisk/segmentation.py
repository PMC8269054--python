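"""Unsupervised spatial segmentation by top-down bisecting k-means.

Spectra (peak-matrix rows) are clustered with correlation distance
d(a, b) = 1 - Pearson(a, b), which is scale-invariant: pixels whose spectra
are multiplicative rescalings of one another always cluster together.

Implementation: each row is centered and scaled to unit norm, after which
correlation distance becomes half the squared Euclidean distance between
the transformed vectors, ||a~ - b~||^2 = 2 (1 - Pearson(a, b)). Standard
2-means on the transformed rows therefore minimizes the within-cluster sum
of correlation dispersions. Bisection proceeds top-down: the cluster with
the largest within-cluster dispersion is split with 2-means (best of
``n_restarts`` seeded initializations) until the requested cluster count is
reached. Zero-variance spectra map to the zero vector, which sits at
correlation distance 1 from everything — a deterministic fallback for the
undefined Pearson coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ROIAnnotation
from .preprocess import PeakMatrix

DEFAULT_RESTARTS = 10


def correlation_transform(X: np.ndarray) -> np.ndarray:
    """Center rows and scale to unit norm; zero-variance rows become zero."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    zero = norms[:, 0] == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance spectra assigned distance 1 to all clusters",
            stacklevel=2,
        )
    norms[norms == 0] = 1.0
    return Xc / norms


def correlation_distance(a: np.ndarray, b: np.ndarray) -> float:
    """d(a, b) = 1 - Pearson(a, b); 1 when either vector has zero variance."""
    ta = correlation_transform(np.atleast_2d(a))[0]
    tb = correlation_transform(np.atleast_2d(b))[0]
    return float(1.0 - ta @ tb)


def within_dispersion(Xt: np.ndarray) -> float:
    """K-means objective of one cluster in transformed space.

    Equals sum_i ||x~_i - c||^2 with c the cluster mean, i.e. twice the mean
    pairwise correlation dispersion; the quantity both the bisection
    selection rule and the 2-means split minimize.
    """
    if len(Xt) == 0:
        return 0.0
    c = Xt.mean(axis=0)
    return float(np.sum((Xt - c) ** 2))


def _two_means(Xt: np.ndarray, rng: np.random.Generator, n_restarts: int) -> np.ndarray:
    """Best-of-restarts Lloyd 2-means on transformed rows; returns 0/1 labels."""
    n = len(Xt)
    best_labels, best_obj = None, np.inf

    # deterministic farthest-pair init plus seeded k-means++-style restarts
    d0 = np.linalg.norm(Xt - Xt[0], axis=1)
    a = int(np.argmax(d0))
    b = int(np.argmax(np.linalg.norm(Xt - Xt[a], axis=1)))
    inits = [(a, b)] if a != b else []
    for _ in range(n_restarts):
        i = int(rng.integers(n))
        d = np.sum((Xt - Xt[i]) ** 2, axis=1)
        if d.sum() > 0:
            j = int(rng.choice(n, p=d / d.sum()))
        else:
            j = int(rng.integers(n))
        if i != j:
            inits.append((i, j))

    for i, j in inits:
        centers = np.stack([Xt[i], Xt[j]])
        labels = np.zeros(n, dtype=int)
        for _ in range(100):
            dist = ((Xt[:, None, :] - centers[None]) ** 2).sum(axis=2)
            new_labels = np.argmin(dist, axis=1)
            if np.array_equal(new_labels, labels) and _ > 0:
                break
            labels = new_labels
            for k in (0, 1):
                if (labels == k).any():
                    centers[k] = Xt[labels == k].mean(axis=0)
        if len(np.unique(labels)) < 2:
            continue
        obj = within_dispersion(Xt[labels == 0]) + within_dispersion(Xt[labels == 1])
        if obj < best_obj - 1e-12:
            best_obj, best_labels = obj, labels.copy()
    if best_labels is None:  # all points identical: arbitrary but deterministic split
        best_labels = np.zeros(n, dtype=int)
        best_labels[0] = 1
    return best_labels


@dataclass
class SegmentationResult:
    """Cluster labels per pixel plus per-cluster mean signatures."""

    labels: np.ndarray
    pixel_table: pd.DataFrame
    signatures: np.ndarray  # (k, n_intervals) cluster means of the raw matrix
    dendrogram: list[dict] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.signatures)


def bisecting_kmeans(
    pm: PeakMatrix,
    n_clusters: int,
    distance: str = "correlation",
    seed: int = 0,
    n_restarts: int = DEFAULT_RESTARTS,
) -> SegmentationResult:
    """Top-down bisecting k-means segmentation of a peak matrix.

    Starts from a single cluster holding all spectra and repeatedly bisects
    the cluster with the largest within-cluster dispersion until
    ``n_clusters`` clusters exist. Deterministic under a fixed seed.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if pm.n_pixels < n_clusters:
        raise ValueError("fewer pixels than requested clusters")
    if distance not in ("correlation", "euclidean"):
        raise ValueError("distance must be 'correlation' or 'euclidean'")
    X = pm.matrix
    Xt = correlation_transform(X) if distance == "correlation" else np.asarray(X, float)
    rng = np.random.default_rng(seed)

    clusters: list[np.ndarray] = [np.arange(pm.n_pixels)]
    dendrogram: list[dict] = []
    while len(clusters) < n_clusters:
        disp = [within_dispersion(Xt[c]) if len(c) > 1 else -1.0 for c in clusters]
        target = int(np.argmax(disp))
        if disp[target] < 0:
            warnings.warn("no splittable cluster left; stopping early", stacklevel=2)
            break
        members = clusters.pop(target)
        split = _two_means(Xt[members], rng, n_restarts)
        left, right = members[split == 0], members[split == 1]
        dendrogram.append(
            {
                "parent_size": len(members),
                "child_sizes": (len(left), len(right)),
                "parent_dispersion": disp[target],
                "child_dispersion": within_dispersion(Xt[left]) + within_dispersion(Xt[right]),
            }
        )
        clusters.insert(target, right)
        clusters.insert(target, left)

    labels = np.empty(pm.n_pixels, dtype=int)
    for k, c in enumerate(clusters):
        labels[c] = k
    signatures = np.stack([X[c].mean(axis=0) for c in clusters])
    return SegmentationResult(labels, pm.pixel_table.copy(), signatures, dendrogram)


def segment_map(result: SegmentationResult, sample: str) -> np.ndarray:
    """Labeled 2-D image for one sample; pixels outside the input are -1."""
    sub = result.pixel_table["sample"] == sample
    if not sub.any():
        raise KeyError(f"sample {sample!r} not in segmentation")
    xs = result.pixel_table.loc[sub, "x"].to_numpy()
    ys = result.pixel_table.loc[sub, "y"].to_numpy()
    img = np.full((ys.max() + 1, xs.max() + 1), -1, dtype=int)
    img[ys, xs] = result.labels[sub.to_numpy()]
    return img


def composition(
    result: SegmentationResult, roi: "ROIAnnotation | str | None" = None
) -> dict[int, float]:
    """Fraction of ROI pixels falling in each cluster; fractions sum to 1."""
    if roi is None:
        mask = np.ones(len(result.labels), dtype=bool)
    elif isinstance(roi, str):
        mask = (result.pixel_table["roi"] == roi).to_numpy()
    else:
        keys = set(map(tuple, roi.table[["x", "y"]].to_numpy()))
        mask = np.array(
            [
                (row.sample == roi.sample_id) and ((row.x, row.y) in keys)
                for row in result.pixel_table.itertuples()
            ]
        )
    if not mask.any():
        raise ValueError("ROI contains no clustered pixels")
    labels = result.labels[mask]
    return {int(k): float(np.mean(labels == k)) for k in np.unique(labels)}


def silhouette_by_k(
    pm: PeakMatrix,
    ks: list[int],
    distance: str = "correlation",
    seed: int = 0,
    n_restarts: int = DEFAULT_RESTARTS,
) -> pd.DataFrame:
    """Mean silhouette score for each candidate cluster count.

    A small model-selection aid: the stopping rule for top-down segmentation
    is not part of the method itself, so cluster counts are compared
    explicitly.
    """
    from sklearn.metrics import silhouette_score

    Xt = correlation_transform(pm.matrix) if distance == "correlation" else pm.matrix
    rows = []
    for k in ks:
        if k < 2 or k >= pm.n_pixels:
            rows.append({"k": k, "silhouette": np.nan})
            continue
        res = bisecting_kmeans(pm, k, distance=distance, seed=seed, n_restarts=n_restarts)
        if len(np.unique(res.labels)) < 2:
            rows.append({"k": k, "silhouette": np.nan})
            continue
        rows.append({"k": k, "silhouette": float(silhouette_score(Xt, res.labels))})
    return pd.DataFrame(rows)
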