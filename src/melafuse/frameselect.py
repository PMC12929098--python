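"""k-NN purity of embedded photobleaching curves and frame-subset selection.

Retraining the full classifier for every candidate set of photobleaching
frames is expensive; instead, candidate frame subsets are compared by
embedding the column-restricted curve matrix into a low-dimensional space
and scoring how label-pure each point's neighborhood is:

    Purity(k) = (1/N) sum_i (1/k) sum_{j in N_k(i)} 1{y_j = y_i}

where ``N_k(i)`` is the set of the k nearest neighbors of point i under a
chosen distance, with the point itself excluded. A purity of 1 means
every local neighborhood is single-class.

The embedding is an injected provider ``(matrix, labels, params, seed) ->
coordinates``. The default is a deterministic PCA projection, which keeps
selection reproducible; a UMAP provider with the same contract is
available when umap-learn is installed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

SUPPORTED_METRICS = ("euclidean", "manhattan", "hamming", "cosine")

EmbeddingProvider = Callable[[np.ndarray, np.ndarray, dict, int], np.ndarray]


@dataclass(frozen=True)
class PurityConfig:
    """Purity-evaluation settings: neighbor count, distance, embed params.

    ``binarize_hamming`` controls how the hamming distance treats
    continuous coordinates: when true (default) each dimension is
    thresholded at its median before comparison; when false raw floats
    are compared for exact inequality, which on continuous embeddings is
    near-degenerate (almost all distances equal 1).
    """

    k: int = 5
    metric: str = "euclidean"
    embed_params: dict = field(default_factory=dict)
    binarize_hamming: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.metric not in SUPPORTED_METRICS:
            raise ValueError(
                f"metric {self.metric!r} not in {SUPPORTED_METRICS}"
            )


@dataclass(frozen=True)
class SelectionResult:
    """Winning frame subset with its purity score and the config used."""

    subset: tuple[int, ...]
    purity: float
    config: PurityConfig

    def __post_init__(self) -> None:
        if len(self.subset) == 0:
            raise ValueError("selected subset must be nonempty")
        if len(set(self.subset)) != len(self.subset):
            raise ValueError("subset indices must be unique")
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must lie in [0, 1]")


def _distance_matrix(points: np.ndarray, metric: str, binarize_hamming: bool) -> np.ndarray:
    if metric == "hamming" and binarize_hamming:
        binary = points > np.median(points, axis=0, keepdims=True)
        return cdist(binary, binary, metric="hamming")
    name = "cityblock" if metric == "manhattan" else metric
    return cdist(points, points, metric=name)


def purity(
    points: np.ndarray,
    labels: Sequence,
    k: int = 5,
    metric: str = "euclidean",
    binarize_hamming: bool = True,
) -> float:
    """Average fraction of each point's k nearest neighbors sharing its label.

    The query point is excluded from its own neighbor set. Ties at the
    k-th distance are broken by ascending sample index, so the score is
    deterministic.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    labels = np.asarray(labels)
    n = len(points)
    if labels.shape[0] != n:
        raise ValueError("labels must align with points")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of points ({n})")
    if not np.isfinite(points).all():
        raise ValueError("purity requires finite coordinates")

    dist = _distance_matrix(points, metric, binarize_hamming)
    np.fill_diagonal(dist, np.inf)
    idx = np.arange(n)
    total = 0.0
    for i in range(n):
        # stable order: ascending distance, ties by ascending sample index
        order = np.lexsort((idx, dist[i]))[:k]
        total += float(np.mean(labels[order] == labels[i]))
    return total / n


def pca_provider(
    matrix: np.ndarray, labels: np.ndarray, params: dict, seed: int
) -> np.ndarray:
    """Deterministic linear projection onto leading principal components.

    Sign-fixed SVD, ignoring labels; ``n_components`` (default 2) is
    capped at the feature count.
    """
    matrix = np.asarray(matrix, dtype=float)
    n_components = min(int(params.get("n_components", 2)), matrix.shape[1])
    centered = matrix - matrix.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    comps = vt[:n_components]
    # fix component signs so the projection is unique
    signs = np.sign(comps[np.arange(len(comps)), np.abs(comps).argmax(axis=1)])
    signs[signs == 0] = 1.0
    return centered @ (comps * signs[:, None]).T


def identity_provider(
    matrix: np.ndarray, labels: np.ndarray, params: dict, seed: int
) -> np.ndarray:
    """Pass-through provider: score purity on the raw curve columns."""
    return np.asarray(matrix, dtype=float)


def umap_provider(
    matrix: np.ndarray, labels: np.ndarray, params: dict, seed: int
) -> np.ndarray:
    """Supervised UMAP embedding (requires umap-learn)."""
    import umap

    reducer = umap.UMAP(
        n_neighbors=int(params.get("n_neighbors", 15)),
        min_dist=float(params.get("min_dist", 0.1)),
        n_components=int(params.get("n_components", 2)),
        metric=params.get("metric", "euclidean"),
        random_state=seed,
    )
    return reducer.fit_transform(np.asarray(matrix, dtype=float), y=np.asarray(labels))


def grid_search_embeddings(
    curves: np.ndarray,
    labels: Sequence,
    grid: Sequence[PurityConfig],
    embed: EmbeddingProvider = pca_provider,
    seed: int = 0,
) -> list[tuple[PurityConfig, float | None]]:
    """Score every config in the grid; rank by purity, descending.

    A provider failure for one config records ``None`` for that config
    and the search continues.
    """
    if len(grid) == 0:
        raise ValueError("parameter grid must be nonempty")
    labels = np.asarray(labels)
    results: list[tuple[PurityConfig, float | None]] = []
    for config in grid:
        try:
            coords = embed(np.asarray(curves, dtype=float), labels, config.embed_params, seed)
            score = purity(
                coords, labels, k=config.k, metric=config.metric,
                binarize_hamming=config.binarize_hamming,
            )
        except Exception:
            results.append((config, None))
            continue
        results.append((config, score))
    return sorted(results, key=lambda cs: -1.0 if cs[1] is None else cs[1], reverse=True)


def prefix_and_window_candidates(n_frames: int) -> list[tuple[int, ...]]:
    """All prefixes (length 1..T) plus all contiguous windows."""
    candidates = [tuple(range(length)) for length in range(1, n_frames + 1)]
    for length in range(1, n_frames):
        for start in range(1, n_frames - length + 1):
            candidates.append(tuple(range(start, start + length)))
    return candidates


def select_frame_subset(
    curves: np.ndarray,
    labels: Sequence,
    candidates: Sequence[Sequence[int]] | None = None,
    config: PurityConfig = PurityConfig(),
    embed: EmbeddingProvider = pca_provider,
    seed: int = 0,
) -> SelectionResult:
    """Pick the frame subset whose embedding maximizes k-NN purity.

    Ties are broken toward the smaller subset, then toward the
    earlier-starting subset, then by candidate order.
    """
    curves = np.asarray(curves, dtype=float)
    labels = np.asarray(labels)
    if candidates is None:
        candidates = prefix_and_window_candidates(curves.shape[1])
    if len(candidates) == 0:
        raise ValueError("candidate list must be nonempty")

    best: tuple[float, int, int] | None = None  # (-purity, size, start) minimized
    best_subset: tuple[int, ...] | None = None
    for cand in candidates:
        subset = tuple(int(i) for i in cand)
        if len(subset) == 0 or len(set(subset)) != len(subset):
            raise ValueError(f"invalid candidate subset {subset}")
        if min(subset) < 0 or max(subset) >= curves.shape[1]:
            raise ValueError(f"candidate {subset} out of range for {curves.shape[1]} frames")
        coords = embed(curves[:, subset], labels, config.embed_params, seed)
        score = purity(
            coords, labels, k=config.k, metric=config.metric,
            binarize_hamming=config.binarize_hamming,
        )
        key = (-score, len(subset), min(subset))
        if best is None or key < best:
            best = key
            best_subset = subset
    assert best is not None and best_subset is not None
    return SelectionResult(subset=best_subset, purity=-best[0], config=config)
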