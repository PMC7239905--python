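"""Two-dimensional embedding of score axes and density-based clustering.

Scores from the sparse factorization are mapped to 2-D with t-SNE, run at
several perplexities with the lowest-cost (KL objective) map retained, and
clusters are found with DBSCAN whose neighbourhood radius is tuned by
maximizing the mean silhouette over non-noise points in the embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

__all__ = ["EmbeddingResult", "ClusterAssignment", "tsne_embed", "dbscan_tune"]


@dataclass
class EmbeddingResult:
    coords: np.ndarray        # (n, 2)
    perplexity: float
    cost: float               # final KL divergence
    n_iter: int
    seed: int


@dataclass
class ClusterAssignment:
    labels: np.ndarray        # (n,), -1 = noise
    eps: float
    min_pts: int
    silhouette: float
    n_clusters: int

    @property
    def assigned(self) -> np.ndarray:
        return self.labels != -1


def tsne_embed(Z: np.ndarray, perplexities=(50, 100), n_iter: int = 100_000,
               seed: int = 0) -> EmbeddingResult:
    """Embed score axes in 2-D, keeping the lowest-cost map across perplexities.

    A perplexity must be below ``n/3`` to be admissible; inadmissible values
    are dropped with a warning and an error is raised when none survive.
    The iteration budget is generous by default; the optimizer stops early
    once the objective plateaus.
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    admissible = [p for p in perplexities if p < n / 3]
    skipped = [p for p in perplexities if p >= n / 3]
    if skipped:
        warnings.warn(f"perplexities {skipped} >= n/3 = {n / 3:.1f} skipped")
    if not admissible:
        raise ValueError(
            f"no admissible perplexity for n={n}; use values below {n / 3:.1f}")
    best: EmbeddingResult | None = None
    for perp in admissible:
        ts = TSNE(n_components=2, perplexity=perp, max_iter=max(250, n_iter),
                  init="pca", random_state=seed)
        coords = ts.fit_transform(Z)
        res = EmbeddingResult(coords, float(perp), float(ts.kl_divergence_),
                              int(ts.n_iter_), seed)
        if best is None or res.cost < best.cost:
            best = res
    return best


def default_eps_grid(coords: np.ndarray, min_pts: int = 10,
                     n_values: int = 30) -> np.ndarray:
    """Candidate radii between the 1st and 90th percentile of the
    k-nearest-neighbour distances (k = min_pts): from radii resolving the
    tightest cores up to the bulk of the k-dist curve, stopping short of the
    outlier tail whose radii bridge distinct clusters.  Scale-free in the
    embedding units."""
    nn = NearestNeighbors(n_neighbors=min_pts + 1).fit(coords)
    dists, _ = nn.kneighbors(coords)
    kd = dists[:, -1]
    lo, hi = np.percentile(kd, [1, 90])
    lo = max(lo, 1e-12)
    hi = max(hi, lo * (1 + 1e-9))
    return np.geomspace(lo, hi, n_values)


def dbscan_tune(coords: np.ndarray, eps_grid: np.ndarray | None = None,
                min_pts: int = 10,
                max_noise_fraction: float = 0.10) -> ClusterAssignment:
    """Silhouette-tuned DBSCAN on the 2-D map.

    For every candidate radius the clustering is scored by the mean
    silhouette over non-noise points (partitions with fewer than two
    clusters are discarded); the highest-silhouette assignment wins, with
    ties going to the smallest radius.  Silhouette over assigned points is
    maximal for a few tiny dense cores with everything else labelled noise,
    so partitions leaving more than ``max_noise_fraction`` of the samples
    unassigned are only considered when no radius does better.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2 * min_pts:
        raise ValueError("need at least 2*min_pts samples")
    if eps_grid is None:
        eps_grid = default_eps_grid(coords, min_pts)
    eps_grid = np.asarray(eps_grid, dtype=float)
    if np.any(eps_grid <= 0) or np.any(np.diff(eps_grid) < 0):
        raise ValueError("eps_grid must be positive and increasing")
    best: ClusterAssignment | None = None
    fallback: ClusterAssignment | None = None
    for eps in eps_grid:
        labels = DBSCAN(eps=float(eps), min_samples=min_pts).fit_predict(coords)
        mask = labels != -1
        k = len(set(labels[mask]))
        if k < 2:
            continue
        sil = float(silhouette_score(coords[mask], labels[mask]))
        cand = ClusterAssignment(labels, float(eps), min_pts, sil, k)
        if (~mask).mean() <= max_noise_fraction:
            if best is None or sil > best.silhouette:
                best = cand
        elif fallback is None or sil > fallback.silhouette:
            fallback = cand
    best = best if best is not None else fallback
    if best is None:
        raise ValueError(
            f"no radius in [{eps_grid[0]:.4g}, {eps_grid[-1]:.4g}] yields >= 2 "
            "clusters; widen the grid or lower min_pts")
    return best
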