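"""Pixel-affinity region correction for class activation maps.

Segmentation scores near class boundaries are unreliable; diffusing per-class
activation along pixel-pair affinities recovers object morphology.  The
machinery: per-class activation maps obtained by projecting pixel features
onto classification weights; an affinity graph over all pixel pairs within a
Euclidean radius (binary same-class labels when ground truth is available,
or exp(-beta * ||f1 - f2||) feature similarities otherwise); and a random-walk
refinement that repeatedly replaces each pixel's activation with the
affinity-weighted average of its neighbourhood.  The transition matrix is the
row-normalized, self-loop-augmented affinity matrix — row-stochastic by
construction, so iterating it drives each class map toward a constant on every
connected component while few iterations merely smooth within-class noise.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import sparse

from .raster_io import ClassScheme, LabelRaster

__all__ = [
    "CAMStack",
    "AffinityGraph",
    "RegionCorrectionConfig",
    "compute_cam",
    "affinity_labels",
    "predict_affinity",
    "random_walk_refine",
    "synthesize_labels",
]


@dataclasses.dataclass(frozen=True)
class RegionCorrectionConfig:
    """Defaults for the correction stage: small-radius local diffusion."""

    radius: int = 5
    beta: float = 2.0
    iterations: int = 8
    background_threshold: float = 0.2

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError(f"radius must be >= 1, got {self.radius}")
        if self.beta < 1:
            raise ValueError(f"beta must be >= 1, got {self.beta}")
        if self.iterations < 0:
            raise ValueError(f"iterations must be >= 0, got {self.iterations}")
        if not 0.0 <= self.background_threshold < 1.0:
            raise ValueError("background_threshold must be in [0, 1)")


@dataclasses.dataclass(frozen=True)
class CAMStack:
    """Per-class activation maps, max-normalized to [0, 1] per class."""

    maps: np.ndarray  # (K, H, W), values in [0, 1]

    def __post_init__(self) -> None:
        m = np.asarray(self.maps, dtype=np.float64)
        if m.ndim != 3:
            raise ValueError(f"maps must be (K, H, W), got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("activation maps must be finite")
        if m.min() < 0.0 or m.max() > 1.0 + 1e-12:
            raise ValueError("normalized activations must lie in [0, 1]")
        object.__setattr__(self, "maps", m)

    @classmethod
    def from_raw(cls, raw: np.ndarray) -> "CAMStack":
        """Clip negatives to zero and max-normalize each class map."""
        m = np.maximum(np.asarray(raw, dtype=np.float64), 0.0)
        peaks = m.reshape(m.shape[0], -1).max(axis=1)
        scale = np.where(peaks > 0, peaks, 1.0)
        return cls(maps=m / scale[:, None, None])

    @property
    def shape(self) -> tuple[int, int]:
        return self.maps.shape[1:]

    @property
    def n_classes(self) -> int:
        return self.maps.shape[0]


@dataclasses.dataclass(frozen=True)
class AffinityGraph:
    """Radius-limited pixel-pair affinities on an ``(H, W)`` grid.

    Edges are undirected and stored once with ``i < j`` in flat (row-major)
    pixel indexing; weights lie in [0, 1].  Self-edges are excluded (the
    refinement adds its own self-loops).
    """

    shape: tuple[int, int]
    edges_i: np.ndarray
    edges_j: np.ndarray
    weights: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        i = np.asarray(self.edges_i, dtype=np.int64)
        j = np.asarray(self.edges_j, dtype=np.int64)
        w = np.asarray(self.weights, dtype=np.float64)
        if not (i.shape == j.shape == w.shape):
            raise ValueError("edge arrays must have equal length")
        if i.size and not np.all(i < j):
            raise ValueError("edges must be stored with i < j (no self-edges)")
        if w.size and (w.min() < 0.0 or w.max() > 1.0):
            raise ValueError("edge weights must lie in [0, 1]")
        object.__setattr__(self, "edges_i", i)
        object.__setattr__(self, "edges_j", j)
        object.__setattr__(self, "weights", w)

    @property
    def n_edges(self) -> int:
        return self.edges_i.size

    def to_sparse(self) -> sparse.csr_matrix:
        """Symmetric affinity matrix without self-loops."""
        n = self.shape[0] * self.shape[1]
        a = sparse.coo_matrix(
            (
                np.concatenate([self.weights, self.weights]),
                (
                    np.concatenate([self.edges_i, self.edges_j]),
                    np.concatenate([self.edges_j, self.edges_i]),
                ),
            ),
            shape=(n, n),
        )
        return a.tocsr()


def _radius_offsets(radius: float) -> list[tuple[int, int]]:
    """Half-plane pixel offsets within Euclidean distance ``radius``."""
    r = int(np.floor(radius))
    offs = []
    for di in range(0, r + 1):
        for dj in range(-r, r + 1):
            if di == 0 and dj <= 0:
                continue  # keep one direction per pair, skip self
            if di * di + dj * dj <= radius * radius:
                offs.append((di, dj))
    return offs


def _pairs_within_radius(
    shape: tuple[int, int], radius: float
) -> tuple[np.ndarray, np.ndarray]:
    """All unordered pixel-index pairs within the radius, vectorized."""
    h, w = shape
    flat = np.arange(h * w).reshape(h, w)
    ii, jj = [], []
    for di, dj in _radius_offsets(radius):
        if di >= h or abs(dj) >= w:
            continue
        if dj >= 0:
            a = flat[: h - di, : w - dj]
            b = flat[di:, dj:]
        else:
            a = flat[: h - di, -dj:]
            b = flat[di:, : w + dj]
        ii.append(a.ravel())
        jj.append(b.ravel())
    if not ii:
        e = np.empty(0, dtype=np.int64)
        return e, e.copy()
    i = np.concatenate(ii)
    j = np.concatenate(jj)
    swap = i > j
    i2 = np.where(swap, j, i)
    j2 = np.where(swap, i, j)
    return i2, j2


def compute_cam(features: np.ndarray, weights: np.ndarray) -> CAMStack:
    """Class activation maps: M_c(x, y) = W_c . f(x, y).

    ``features`` is ``(H, W, D)``; ``weights`` is ``(K, D)``.  Negative
    activations are clipped to zero and each class map is max-normalized.
    """
    f = np.asarray(features, dtype=np.float64)
    wt = np.asarray(weights, dtype=np.float64)
    if f.ndim != 3 or wt.ndim != 2 or f.shape[2] != wt.shape[1]:
        raise ValueError(
            f"feature dim {f.shape} incompatible with weight dim {wt.shape}"
        )
    raw = np.einsum("hwd,kd->khw", f, wt)
    return CAMStack.from_raw(raw)


def affinity_labels(labels: LabelRaster, radius: float) -> AffinityGraph:
    """Ground-truth binary affinities: 1 iff the two pixel classes are equal.

    Pairs touching an ignore pixel are dropped entirely.
    """
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    i, j = _pairs_within_radius(labels.shape, radius)
    flat = labels.data.ravel()
    keep = (flat[i] != labels.scheme.ignore_index) & (
        flat[j] != labels.scheme.ignore_index
    )
    i, j = i[keep], j[keep]
    w = (flat[i] == flat[j]).astype(np.float64)
    return AffinityGraph(shape=labels.shape, edges_i=i, edges_j=j, weights=w,
                         radius=float(radius))


def predict_affinity(
    features: np.ndarray, radius: float, beta: float = 2.0
) -> AffinityGraph:
    """Feature-derived affinities exp(-||f1 - f2||)^beta = exp(-beta d).

    ``features`` is ``(H, W, D)``.  The exponent penalizes weak similarities,
    confining propagation to genuinely alike surroundings; weights are in
    (0, 1].
    """
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    if beta < 1:
        raise ValueError(f"beta must be >= 1, got {beta}")
    f = np.asarray(features, dtype=np.float64)
    if f.ndim != 3:
        raise ValueError(f"features must be (H, W, D), got {f.shape}")
    h, w, d = f.shape
    i, j = _pairs_within_radius((h, w), radius)
    flat = f.reshape(-1, d)
    dist = np.linalg.norm(flat[i] - flat[j], axis=1)
    weights = np.exp(-beta * dist)
    return AffinityGraph(shape=(h, w), edges_i=i, edges_j=j, weights=weights,
                         radius=float(radius))


def transition_matrix(graph: AffinityGraph) -> sparse.csr_matrix:
    """Row-stochastic transition: row-normalized self-loop-augmented affinity."""
    n = graph.shape[0] * graph.shape[1]
    a = graph.to_sparse() + sparse.identity(n, format="csr")
    deg = np.asarray(a.sum(axis=1)).ravel()
    t = sparse.diags(1.0 / deg) @ a
    # row-stochasticity is a hard invariant of the construction
    rowsum = np.asarray(t.sum(axis=1)).ravel()
    assert np.allclose(rowsum, 1.0), "transition matrix rows must sum to 1"
    return t.tocsr()


def random_walk_refine(
    cams: CAMStack, graph: AffinityGraph, iterations: int
) -> CAMStack:
    """Diffuse each class map ``t`` times along the affinity transition matrix.

    Each step replaces a pixel's activation by the affinity-weighted average
    over its radius neighbourhood (self-loop included).  Averaging is convex,
    so the output stays inside [0, 1] without rescaling; per-class
    re-normalization is deliberately NOT applied, because dividing a
    near-empty class map by its own small maximum would inflate pure noise
    into a competitive activation.  ``t = 0``, or a graph with no edges,
    leaves the maps unchanged.
    """
    if iterations < 0:
        raise ValueError(f"iterations must be >= 0, got {iterations}")
    if graph.shape != cams.shape:
        raise ValueError(
            f"graph shape {graph.shape} does not cover CAM shape {cams.shape}"
        )
    if iterations == 0:
        return cams
    t = transition_matrix(graph)
    k = cams.n_classes
    m = cams.maps.reshape(k, -1).T  # (N, K)
    for _ in range(iterations):
        m = t @ m
    m = np.clip(m, 0.0, 1.0)  # guard numeric round-off only
    return CAMStack(maps=m.T.reshape(cams.maps.shape))


def synthesize_labels(
    refined: CAMStack,
    scheme: ClassScheme,
    background_threshold: float = 0.2,
) -> LabelRaster:
    """Argmax the refined activations into a label raster.

    The K class maps are taken in the order of the scheme's scored (non-ignore)
    classes.  Pixels whose best activation falls below the threshold become
    ignore.
    """
    if not 0.0 <= background_threshold < 1.0:
        raise ValueError("background_threshold must be in [0, 1)")
    if refined.n_classes != scheme.n_scored:
        raise ValueError(
            f"{refined.n_classes} maps for {scheme.n_scored} scored classes"
        )
    scored = np.array(
        [i for i in range(scheme.n_classes) if i != scheme.ignore_index]
    )
    best = np.argmax(refined.maps, axis=0)
    data = scored[best]
    data[refined.maps.max(axis=0) < background_threshold] = scheme.ignore_index
    return LabelRaster(data=data, scheme=scheme)
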