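"""Compartmentalization: clustering, linear unmixing, difference peaks.

Segmentation runs k-means on the leading PCA scores of vector-normalized
spectra (unit Euclidean norm), so clusters reflect spectral *shape* rather
than brightness.  Linear unmixing ("component imaging") models every pixel as
a non-negative combination of endmember spectra; endmembers are sought among
the observed pixel spectra by successive simplex-volume maximization on
PCA-reduced scores (a vertex-seeking procedure: under the pure-pixel
assumption the extreme points of the data simplex are the pure spectra), and
per-pixel abundances come from non-negative least squares.  Because the
endmember sets are nested in the component count, the reconstruction residual
is weakly decreasing as components are added.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import nnls
from scipy.signal import find_peaks
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .core import HyperCube, Spectrum
from .errors import ConfigError, SelectionError

__all__ = [
    "ClusterResult",
    "UnmixResult",
    "kmeans_cluster",
    "select_k",
    "true_component_analysis",
    "cluster_mean_spectra",
    "difference_peaks",
]


@dataclass
class ClusterResult:
    """Hard segmentation: per-pixel labels plus per-cluster mean spectra.

    ``labels`` is (height, width) int with -1 at masked pixels; ``inertia``
    is the within-cluster sum of squares in the feature space the clustering
    ran in (PCA scores of normalized spectra).
    """

    k: int
    labels: np.ndarray
    mean_spectra: list[Optional[Spectrum]]
    inertia: float
    seed: int


@dataclass
class UnmixResult:
    """Linear unmixing: endmember spectra with non-negative abundances.

    ``abundances`` is (height, width, n_components); ``residual`` is the
    per-pixel RMS of the reconstruction error (NaN at masked pixels).
    """

    n_components: int
    endmembers: list[Spectrum]
    abundances: np.ndarray
    residual: np.ndarray


def _valid_spectra(cube: HyperCube) -> tuple[np.ndarray, np.ndarray]:
    valid = cube.valid_mask()
    return cube.data[valid], valid


def _shape_features(X: np.ndarray, n_pcs: int, seed: int = 0) -> np.ndarray:
    """PCA scores of L2-normalized spectra (the clustering feature space)."""
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    Xn = X / norms
    n_comp = min(n_pcs, Xn.shape[1], max(Xn.shape[0] - 1, 1))
    return PCA(n_components=n_comp, random_state=seed).fit_transform(Xn)


def kmeans_cluster(cube: HyperCube, k: int, seed: int = 0, n_pcs: int = 10) -> ClusterResult:
    """K-means segmentation of the cube's valid pixels.

    k-means++ initialization with 10 restarts, Euclidean distance on the top
    ``n_pcs`` PCA scores of vector-normalized spectra; the best-inertia run is
    returned and the result is deterministic for a fixed ``seed``.  Reported
    mean spectra are arithmetic means of the member pixels' *original*
    (unnormalized) spectra.
    """
    X, valid = _valid_spectra(cube)
    if k < 1:
        raise ConfigError("k must be >= 1")
    if k > X.shape[0]:
        raise ConfigError(f"k={k} exceeds the {X.shape[0]} unmasked pixels")
    scores = _shape_features(X, n_pcs, seed)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(scores)
    labels = np.full(cube.data.shape[:2], -1, dtype=int)
    labels[valid] = km.labels_
    result = ClusterResult(
        k=k,
        labels=labels,
        mean_spectra=[],
        inertia=float(km.inertia_),
        seed=seed,
    )
    result.mean_spectra = cluster_mean_spectra(cube, labels)
    return result


def select_k(
    cube: HyperCube, k_range: Sequence[int], seed: int = 0, n_pcs: int = 10
) -> tuple[int, dict[int, float]]:
    """Choose the cluster count by mean silhouette on the PCA shape scores.

    Returns ``(chosen_k, profile)`` with the silhouette for every k in
    ``k_range``; ties break toward the smaller k.
    """
    X, _ = _valid_spectra(cube)
    ks = sorted(int(k) for k in k_range)
    if not ks or ks[0] < 2 or ks[-1] > X.shape[0] - 1:
        raise ConfigError("k_range must lie within [2, unmasked pixels - 1]")
    if np.allclose(X, X[0], rtol=1e-12, atol=1e-12 * max(np.abs(X).max(), 1.0)):
        raise SelectionError("cube is degenerate: all pixel spectra are identical")
    scores = _shape_features(X, n_pcs, seed)
    profile: dict[int, float] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(scores)
        if len(np.unique(km.labels_)) < 2:
            profile[k] = float("nan")
            continue
        profile[k] = float(silhouette_score(scores, km.labels_))
    best_k, best_s = None, -np.inf
    for k in ks:  # ascending: ties go to the smaller k
        s = profile[k]
        if np.isfinite(s) and s > best_s:
            best_k, best_s = k, s
    if best_k is None:
        raise SelectionError("no k in range produced a valid silhouette")
    return best_k, profile


def _successive_vertices(Y: np.ndarray, n: int, rng: np.random.Generator) -> list[int]:
    """Indices of ``n`` simplex vertices by successive volume maximization.

    Starts from the point farthest from the centroid and repeatedly adds the
    point farthest from the affine hull of the current set — nested in ``n``,
    and exact under the pure-pixel assumption.  The rng breaks exact
    distance ties reproducibly.
    """
    centroid = Y.mean(axis=0)
    dist = np.linalg.norm(Y - centroid, axis=1)
    chosen = [int(_argmax_tiebreak(dist, rng))]
    basis: list[np.ndarray] = []
    for _ in range(1, n):
        rel = Y - Y[chosen[0]]
        resid = rel.copy()
        for b in basis:
            resid -= np.outer(resid @ b, b)
        dist = np.linalg.norm(resid, axis=1)
        dist[chosen] = -np.inf
        nxt = int(_argmax_tiebreak(dist, rng))
        chosen.append(nxt)
        v = rel[nxt].copy()
        for b in basis:
            v -= (v @ b) * b
        nv = np.linalg.norm(v)
        if nv > 0:
            basis.append(v / nv)
    return chosen


def _argmax_tiebreak(values: np.ndarray, rng: np.random.Generator) -> int:
    m = values.max()
    ties = np.flatnonzero(values == m)
    return int(ties[0] if len(ties) == 1 else rng.choice(ties))


def true_component_analysis(cube: HyperCube, n_components: int, seed: int = 0) -> UnmixResult:
    """Endmember extraction plus non-negative least-squares abundance maps.

    An open re-specification of proprietary "true component analysis"
    (component imaging as a linear combination of spectra): endmembers are
    observed pixel spectra chosen by simplex-volume maximization on PCA
    scores; abundances solve ``min ||S - E a||`` subject to ``a >= 0`` per
    pixel.  Approximation of the closed-source procedure, not a clone.
    """
    X, valid = _valid_spectra(cube)
    if n_components < 1:
        raise ConfigError("n_components must be >= 1")
    if n_components > min(cube.n_channels, X.shape[0]):
        raise ConfigError("n_components exceeds min(channels, pixels)")
    rng = np.random.default_rng(seed)
    p = min(max(n_components - 1, 1), X.shape[1], X.shape[0] - 1)
    Y = PCA(n_components=p, random_state=seed).fit_transform(X)
    idx = _successive_vertices(Y, n_components, rng)
    E = X[idx].T  # (channels, K)
    endmembers = [Spectrum(cube.axis, X[i].copy()) for i in idx]

    h, w = cube.data.shape[:2]
    abundances = np.zeros((h, w, n_components))
    residual = np.full((h, w), np.nan)
    coords = np.argwhere(valid)
    for n, (r, c) in enumerate(coords):
        s = cube.data[r, c]
        try:
            a, rnorm = nnls(E, s)
        except RuntimeError:
            warnings.warn(f"NNLS did not converge at pixel ({r}, {c}); flagged", stacklevel=2)
            abundances[r, c] = np.nan
            continue
        abundances[r, c] = a
        residual[r, c] = rnorm / np.sqrt(cube.n_channels)
    return UnmixResult(
        n_components=n_components,
        endmembers=endmembers,
        abundances=abundances,
        residual=residual,
    )


def cluster_mean_spectra(cube: HyperCube, labels: np.ndarray) -> list[Optional[Spectrum]]:
    """Arithmetic mean spectrum per label over unmasked pixels.

    Empty clusters yield ``None`` (mean undefined) with a warning.
    """
    labels = np.asarray(labels)
    if labels.shape != cube.data.shape[:2]:
        raise ConfigError("label map shape does not match cube grid")
    valid = cube.valid_mask()
    k = int(labels[valid].max()) + 1 if valid.any() else 0
    out: list[Optional[Spectrum]] = []
    for lab in range(k):
        sel = valid & (labels == lab)
        if not sel.any():
            warnings.warn(f"cluster {lab} is empty; mean spectrum undefined", stacklevel=2)
            out.append(None)
            continue
        out.append(Spectrum(cube.axis, cube.data[sel].mean(axis=0)))
    return out


def difference_peaks(
    mean_spectra: Sequence[Optional[Spectrum]], min_prominence: float = 0.0
) -> list[list[tuple[float, float]]]:
    """Candidate assignment bands per cluster from contrast spectra.

    For each cluster the contrast is its mean spectrum minus the mean of all
    *other* clusters' spectra; local maxima with prominence above
    ``min_prominence`` are returned as ``(position_cm1, prominence)`` in
    descending prominence.  Clusters whose mean is undefined get an empty
    list.
    """
    present = [s for s in mean_spectra if s is not None]
    if len(present) < 2:
        raise ConfigError("difference peaks need at least 2 cluster mean spectra")
    axis = present[0].axis
    for s in present[1:]:
        if not np.array_equal(s.axis.values, axis.values):
            raise ConfigError("cluster mean spectra must share one axis")
    out: list[list[tuple[float, float]]] = []
    for i, spec in enumerate(mean_spectra):
        if spec is None:
            out.append([])
            continue
        others = [s for j, s in enumerate(mean_spectra) if j != i and s is not None]
        if not others:
            out.append([])
            continue
        contrast = spec.intensity - np.mean([s.intensity for s in others], axis=0)
        idx, props = find_peaks(contrast, prominence=max(min_prominence, 0.0))
        if len(idx) == 0:
            out.append([])
            continue
        proms = props["prominences"]
        order = np.argsort(-proms)
        out.append([(float(axis.values[j]), float(p)) for j, p in zip(idx[order], proms[order])])
    return out
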