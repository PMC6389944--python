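"""Streamline shape basis (PCA), weight-space clustering and bundle
segmentation.

Centred, re-parameterised streamlines (see :mod:`cnvtract.streamlines`)
live in a 3·k-dimensional feature space. A PCA of the pooled feature
vectors yields an orthonormal *shape basis*; each streamline is then a
short weight vector (its projection onto the retained basis, default
~95 % of shape variance). Weight vectors are clustered with k-means
(faithful setting k = 800), clusters are mapped to anatomical bundle
labels from a labelled reference set, and per-bundle *shape descriptors*
(mean projection weight per retained component) summarise each subject's
bundle geometry. Descriptor signs are arbitrary up to eigenvector
orientation; a fixed sign convention (largest-|element| positive) makes
runs comparable.
"""

from __future__ import annotations

import json
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from cnvtract.streamlines import Streamline, Tractogram, streamlines_to_features

__all__ = [
    "BUNDLE_VOCABULARY",
    "UNASSIGNED",
    "ShapeModel",
    "ClusterModel",
    "BundleShapeDescriptors",
    "fit_shape_pca",
    "project",
    "cluster_weights",
    "assign_clusters",
    "membership_histogram",
    "train_bundle_map",
    "segment_bundles",
    "shape_descriptors",
]

UNASSIGNED = "unassigned"

#: The 19-bundle vocabulary: five bilateral association fasciculi, the
#: dorsal and parahippocampal cingulum, the fornix branches, and the
#: three corpus-callosum segments.
BUNDLE_VOCABULARY: tuple[str, ...] = (
    "arcuate_L", "arcuate_R",
    "uncinate_L", "uncinate_R",
    "ilf_L", "ilf_R",
    "slf_L", "slf_R",
    "ifof_L", "ifof_R",
    "cingulum_dorsal_L", "cingulum_dorsal_R",
    "cingulum_parahippocampal_L", "cingulum_parahippocampal_R",
    "fornix_L", "fornix_R",
    "cc_splenium", "cc_body", "cc_genu",
)


@dataclass
class ShapeModel:
    """Orthonormal PCA shape basis over streamline feature vectors."""

    mean_vector: np.ndarray          # (d,)
    basis: np.ndarray                # (m, d), rows orthonormal
    eigenvalues: np.ndarray          # (m,), non-increasing
    variance_retained: float         # achieved fraction, >= target
    total_variance: float            # trace of the sample covariance

    @property
    def n_components(self) -> int:
        return self.basis.shape[0]

    def __post_init__(self) -> None:
        G = self.basis @ self.basis.T
        if not np.allclose(G, np.eye(self.n_components), atol=1e-8):
            raise ValueError("shape basis rows are not orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be non-increasing")

    def save(self, prefix: str | os.PathLike) -> None:
        """Serialise to ``<prefix>.json`` (metadata) + ``<prefix>.npz`` (arrays)."""
        np.savez(f"{prefix}.npz", mean_vector=self.mean_vector,
                 basis=self.basis, eigenvalues=self.eigenvalues)
        with open(f"{prefix}.json", "w") as fh:
            json.dump({"kind": "ShapeModel",
                       "n_components": self.n_components,
                       "variance_retained": self.variance_retained,
                       "total_variance": self.total_variance,
                       "arrays": os.path.basename(f"{prefix}.npz")}, fh, indent=2)

    @classmethod
    def load(cls, prefix: str | os.PathLike) -> "ShapeModel":
        with open(f"{prefix}.json") as fh:
            meta = json.load(fh)
        arrs = np.load(f"{prefix}.npz")
        return cls(mean_vector=arrs["mean_vector"], basis=arrs["basis"],
                   eigenvalues=arrs["eigenvalues"],
                   variance_retained=meta["variance_retained"],
                   total_variance=meta["total_variance"])


@dataclass
class ClusterModel:
    """k-means centroids in shape-weight space plus cluster→bundle labels."""

    centroids: np.ndarray                       # (K, m)
    cluster_to_bundle: dict[int, str] = field(default_factory=dict)
    seed: int = 0

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.ndim != 2 or self.centroids.shape[0] < 1:
            raise ValueError("centroids must be a non-empty (K, m) array")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")
        bad = [c for c in self.cluster_to_bundle if not 0 <= c < self.n_clusters]
        if bad:
            raise ValueError(f"cluster ids out of range: {bad}")

    def save(self, prefix: str | os.PathLike) -> None:
        np.savez(f"{prefix}.npz", centroids=self.centroids)
        with open(f"{prefix}.json", "w") as fh:
            json.dump({"kind": "ClusterModel", "seed": self.seed,
                       "n_clusters": self.n_clusters,
                       "cluster_to_bundle": {str(k): v for k, v
                                             in self.cluster_to_bundle.items()},
                       "arrays": os.path.basename(f"{prefix}.npz")}, fh, indent=2)

    @classmethod
    def load(cls, prefix: str | os.PathLike) -> "ClusterModel":
        with open(f"{prefix}.json") as fh:
            meta = json.load(fh)
        arrs = np.load(f"{prefix}.npz")
        return cls(centroids=arrs["centroids"], seed=meta["seed"],
                   cluster_to_bundle={int(k): v for k, v
                                      in meta["cluster_to_bundle"].items()})


@dataclass
class BundleShapeDescriptors:
    """Per-bundle shape descriptors: mean projection weight per component.

    ``values`` is NaN-filled (and ``missing`` is True) when fewer than the
    configured minimum number of streamlines contributed — a missing
    descriptor is never silently zero.
    """

    bundle: str
    values: np.ndarray
    n_streamlines: int
    missing: bool = False


def fit_shape_pca(vectors: np.ndarray | Sequence[np.ndarray],
                  variance_target: float = 0.95,
                  n_components: int | None = None) -> ShapeModel:
    """Fit the PCA shape basis retaining ``variance_target`` of variance.

    ``m`` is the smallest component count whose cumulative explained
    variance reaches the target; alternatively a fixed ``n_components``
    (the canonical analysis keeps the first seven eigenvectors, which
    carry ~95 % of shape variance on whole-brain tractograms) can be
    requested directly. Eigenvector signs are fixed so each component's
    largest-magnitude element is positive.
    """
    X = np.asarray(list(vectors) if not isinstance(vectors, np.ndarray) else vectors,
                   dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two feature vectors")
    if not 0.0 < variance_target <= 1.0:
        raise ValueError("variance_target must be in (0, 1]")
    if np.allclose(X, X[0], atol=1e-12):
        raise ValueError("zero variance: all feature vectors are identical")
    pca = PCA(svd_solver="full").fit(X)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    if n_components is not None:
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        m = min(int(n_components), len(ratios))
    else:
        m = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
        m = min(m, len(ratios))
    basis = pca.components_[:m].copy()
    for j in range(m):
        i = int(np.argmax(np.abs(basis[j])))
        if basis[j, i] < 0:
            basis[j] = -basis[j]
    return ShapeModel(mean_vector=pca.mean_.copy(), basis=basis,
                      eigenvalues=pca.explained_variance_[:m].copy(),
                      variance_retained=float(cum[m - 1]),
                      total_variance=float(pca.explained_variance_.sum()))


def project(model: ShapeModel, v: np.ndarray) -> np.ndarray:
    """Project feature vector(s) onto the shape basis.

    Accepts a single vector ``(d,)`` or a stack ``(n, d)``; returns
    weights ``basis · (v − mean)`` of length ``m`` (or ``(n, m)``).
    """
    v = np.asarray(v, dtype=float)
    d = model.mean_vector.shape[0]
    if v.shape[-1] != d:
        raise ValueError(f"vector length {v.shape[-1]} != model dimension {d}")
    return (v - model.mean_vector) @ model.basis.T


def cluster_weights(weights: np.ndarray, K: int = 800, seed: int = 0,
                    n_init: int = 10,
                    init: np.ndarray | None = None) -> ClusterModel:
    """Cluster streamline weight vectors with k-means (k-means++ init).

    Deterministic for a given ``seed``; the best of ``n_init`` restarts by
    inertia is kept. An explicit ``init`` array of starting centroids may
    be supplied instead (single run), which makes the Lloyd iteration
    directly comparable against reference implementations. Raises if
    there are fewer points than clusters.
    """
    W = np.asarray(weights, dtype=float)
    if W.ndim != 2:
        raise ValueError("weights must be (n, m)")
    if W.shape[0] < K:
        raise ValueError(
            f"{W.shape[0]} weight vectors < K={K}; use a smaller K "
            f"(e.g. K=min(800, n_streamlines // 10))")
    if init is not None:
        km = KMeans(n_clusters=K, init=np.asarray(init, dtype=float),
                    n_init=1, random_state=seed).fit(W)
    else:
        km = KMeans(n_clusters=K, init="k-means++", n_init=n_init,
                    random_state=seed).fit(W)
    return ClusterModel(centroids=km.cluster_centers_.copy(), seed=seed)


def assign_clusters(clusters: ClusterModel, weights: np.ndarray) -> np.ndarray:
    """Nearest-centroid (Euclidean) cluster id for each weight vector."""
    W = np.atleast_2d(np.asarray(weights, dtype=float))
    return np.argmin(cdist(W, clusters.centroids), axis=1)


def membership_histogram(assignments: Sequence[int], K: int,
                         normalise: bool = False) -> np.ndarray:
    """Histogram of one subject's streamline cluster memberships.

    Un-normalised entries sum to the streamline count; normalised entries
    sum to one (an empty subject stays all-zero).
    """
    a = np.asarray(assignments, dtype=int)
    if a.size and (a.min() < 0 or a.max() >= K):
        raise ValueError(f"cluster ids must lie in [0, {K})")
    h = np.bincount(a, minlength=K).astype(float)
    if normalise and h.sum() > 0:
        h = h / h.sum()
    return h


def train_bundle_map(clusters: ClusterModel, weights: np.ndarray,
                     labels: Sequence[str],
                     vocabulary: Sequence[str] = BUNDLE_VOCABULARY) -> ClusterModel:
    """Label each cluster by majority vote of a labelled reference set.

    Clusters receiving no reference streamlines stay unlabelled (their
    future members are ``unassigned``). Labels outside the bundle
    vocabulary are rejected.
    """
    labels = list(labels)
    vocab = set(vocabulary)
    bad = sorted({l for l in labels if l not in vocab and l != UNASSIGNED})
    if bad:
        raise ValueError(f"labels outside bundle vocabulary: {bad}")
    ids = assign_clusters(clusters, weights)
    mapping: dict[int, str] = {}
    for c in np.unique(ids):
        votes = Counter(labels[i] for i in np.flatnonzero(ids == c))
        mapping[int(c)] = votes.most_common(1)[0][0]
    clusters.cluster_to_bundle = mapping
    return clusters


def segment_bundles(tractogram: Tractogram, model: ShapeModel,
                    clusters: ClusterModel, n_knots: int | None = None,
                    ) -> dict[str, list[int]]:
    """Assign each streamline the bundle label of its nearest cluster.

    Returns a map bundle label → streamline indices, with label
    ``"unassigned"`` for streamlines landing in unlabelled clusters.
    Requires a populated cluster→bundle map (see :func:`train_bundle_map`).
    """
    if not clusters.cluster_to_bundle:
        raise ValueError("cluster_to_bundle map is empty; train it on a "
                         "labelled reference set first")
    if n_knots is None:
        n_knots = model.mean_vector.shape[0] // 3
    X = streamlines_to_features(tractogram.streamlines, n_knots=n_knots)
    out: dict[str, list[int]] = {}
    if X.shape[0] == 0:
        return out
    ids = assign_clusters(clusters, project(model, X))
    for i, c in enumerate(ids):
        label = clusters.cluster_to_bundle.get(int(c), UNASSIGNED)
        out.setdefault(label, []).append(i)
    return out


def shape_descriptors(weights: np.ndarray, model: ShapeModel, bundle: str,
                      min_streamlines: int = 5) -> BundleShapeDescriptors:
    """Per-bundle descriptor vector: mean projection weight per component.

    With fewer than ``min_streamlines`` contributing streamlines the
    descriptor is marked missing (NaN values), never zero-filled.
    """
    W = np.atleast_2d(np.asarray(weights, dtype=float))
    if W.size == 0:
        W = W.reshape(0, model.n_components)
    if W.shape[0] < min_streamlines:
        return BundleShapeDescriptors(bundle=bundle,
                                      values=np.full(model.n_components, np.nan),
                                      n_streamlines=W.shape[0], missing=True)
    if W.shape[1] != model.n_components:
        raise ValueError("weight dimension does not match model components")
    return BundleShapeDescriptors(bundle=bundle, values=W.mean(axis=0),
                                  n_streamlines=W.shape[0])
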