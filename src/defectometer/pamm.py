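"""Density-based motif detection in projected SOAP space (PAMM-style).

The pipeline estimates the probability density of the 3-D PCA projections on
a farthest-point-sampled grid with an anisotropic Gaussian KDE, associates
every local density maximum with a microcluster by quick-shift mode seeking,
measures microcluster robustness with a bootstrap (73 resamples by default)
and condenses microclusters into macroclusters by cutting the average-linkage
dendrogram built on one minus the bootstrap stability matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "GridSample",
    "MicroclusterModel",
    "MacroMap",
    "farthest_point_sample",
    "kde_density",
    "mode_cluster",
    "assign_microstates",
    "bootstrap_stability",
    "cut_macroclusters",
    "fit_microclusters",
]


@dataclass
class GridSample:
    """Farthest-point-sampled subset of the dataset used as the KDE grid."""

    indices: np.ndarray
    points: np.ndarray


@dataclass
class MicroclusterModel:
    """Fitted microcluster model: grid, densities, labels, stability, tree."""

    grid: GridSample
    density: np.ndarray
    grid_labels: np.ndarray
    modes: np.ndarray
    point_labels: np.ndarray
    stability: np.ndarray = None  # type: ignore[assignment]
    merge_tree: np.ndarray = None  # type: ignore[assignment]

    @property
    def n_micro(self) -> int:
        return int(self.grid_labels.max()) + 1


@dataclass
class MacroMap:
    """Microcluster -> macrocluster assignment."""

    micro_to_macro: np.ndarray
    K: int

    def apply(self, micro_labels: np.ndarray) -> np.ndarray:
        return self.micro_to_macro[np.asarray(micro_labels, int)]


def farthest_point_sample(points: np.ndarray, n_grid: int, seed: int) -> GridSample:
    """Greedy max-min subset; first point drawn uniformly with ``seed``.

    Distance ties are broken by the lowest index.
    """
    X = np.asarray(points, dtype=float)
    N = X.shape[0]
    if n_grid > N:
        raise ValueError(f"n_grid={n_grid} exceeds dataset size {N}")
    rng = np.random.default_rng(seed)
    first = int(rng.integers(N))
    chosen = np.empty(n_grid, dtype=int)
    chosen[0] = first
    d2 = np.sum((X - X[first]) ** 2, axis=1)
    for k in range(1, n_grid):
        nxt = int(np.argmax(d2))  # argmax takes the lowest index on ties
        chosen[k] = nxt
        d2 = np.minimum(d2, np.sum((X - X[nxt]) ** 2, axis=1))
    return GridSample(indices=chosen, points=X[chosen])


def _silverman_factor(n: int, k: int) -> float:
    return (4.0 / (n * (k + 2.0))) ** (1.0 / (k + 4.0))


def kde_density(points: np.ndarray, grid: GridSample,
                n_localization: int | None = None, ridge: float = 1e-8) -> np.ndarray:
    """Anisotropic Gaussian KDE of the dataset evaluated at the grid points.

    The bandwidth matrix at each grid point is the covariance of its
    ``n_localization`` nearest dataset points (default ceil(N/4), at least
    k+1), scaled by the squared Silverman factor; near-singular local
    covariances are regularized by a ridge proportional to their trace.
    A large localization fraction keeps the bandwidth representative of a
    whole density basin rather than of its core, which is what makes
    mode-seeking stable on tightly clustered descriptor data.
    """
    X = np.asarray(points, dtype=float)
    N, k = X.shape
    if N < k + 1:
        raise ValueError("need at least k+1 points for a covariance bandwidth")
    n_loc = n_localization or max(k + 1, int(np.ceil(N / 4)))
    n_loc = min(n_loc, N)
    h2 = _silverman_factor(N, k) ** 2
    tree = cKDTree(X)
    _, nn = tree.query(grid.points, k=n_loc)
    nn = np.atleast_2d(nn)
    G = grid.points.shape[0]

    # local anisotropic bandwidths H_g (k x k), ridge-regularized
    local = X[nn]                                    # (G, n_loc, k)
    mu = local.mean(axis=1, keepdims=True)
    dev = local - mu
    cov = np.einsum("gni,gnj->gij", dev, dev) / max(n_loc - 1, 1)
    tr = np.trace(cov, axis1=1, axis2=2)
    tr = np.where(tr > 0, tr, 1.0)
    eye = np.eye(k)
    H = h2 * (cov + (ridge * tr / k)[:, None, None] * eye)
    detH = np.linalg.det(H)
    bad = ~(detH > 0) | ~np.isfinite(detH)
    if np.any(bad):
        logger.info("regularizing %d singular local covariances", int(bad.sum()))
        H[bad] = h2 * (cov[bad] + (1e-4 * tr[bad] / k)[:, None, None] * eye)
        detH = np.linalg.det(H)
    Hinv = np.linalg.inv(H)
    norm = (2.0 * np.pi) ** (k / 2.0) * np.sqrt(detH)

    dens = np.empty(G)
    chunk = max(1, int(4e6 / max(N, 1)))
    for s in range(0, G, chunk):
        sl = slice(s, min(s + chunk, G))
        diff = X[None, :, :] - grid.points[sl, None, :]          # (g, N, k)
        q = np.einsum("gni,gij,gnj->gn", diff, Hinv[sl], diff, optimize=True)
        dens[sl] = np.exp(-0.5 * q).sum(axis=1) / (N * norm[sl])
    return np.maximum(dens, np.finfo(float).tiny)


def mode_cluster(grid: GridSample, density: np.ndarray, lambda_qs: float = 3.0):
    """Quick-shift mode seeking on the grid.

    Each grid point links to its nearest grid point of strictly higher
    density within ``lambda_qs`` times the median nearest-neighbour grid
    spacing; link-free points are modes.  Density ties break toward the
    lower index.

    Returns (grid_labels, modes).
    """
    G = grid.points
    n = G.shape[0]
    dens = np.asarray(density, dtype=float)
    tree = cKDTree(G)
    nn_d, _ = tree.query(G, k=min(2, n))
    spacing = float(np.median(nn_d[:, -1])) if n > 1 else 1.0
    radius = lambda_qs * spacing
    # rank with index tie-break: higher density wins, lower index wins ties
    order = np.lexsort((np.arange(n), -dens))
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)  # rank 0 = highest density
    parent = np.full(n, -1, dtype=int)
    chunk = max(1, int(4e6 / max(n, 1)))
    for s in range(0, n, chunk):
        sl = slice(s, min(s + chunk, n))
        d2 = np.sum((G[sl, None, :] - G[None, :, :]) ** 2, axis=2)
        ok = (d2 <= radius * radius) & (rank[None, :] < rank[sl, None])
        d2 = np.where(ok, d2, np.inf)
        best = np.argmin(d2, axis=1)  # lowest index on distance ties
        has = np.isfinite(d2[np.arange(d2.shape[0]), best])
        parent[sl] = np.where(has, best, -1)
    labels = np.full(n, -1, dtype=int)
    modes = []
    for i in order:  # process in descending density: parents resolve first
        if parent[i] < 0:
            labels[i] = len(modes)
            modes.append(i)
        else:
            labels[i] = labels[parent[i]]
    return labels, np.array(modes, dtype=int)


def assign_microstates(points: np.ndarray, grid: GridSample,
                       grid_labels: np.ndarray) -> np.ndarray:
    """Each dataset vector inherits the microcluster of its nearest grid point."""
    tree = cKDTree(grid.points)
    _, nearest = tree.query(np.asarray(points, dtype=float))
    return np.asarray(grid_labels)[nearest]


def _cluster_once(X: np.ndarray, n_grid: int, seed: int, lambda_qs: float,
                  n_localization: int | None):
    grid = farthest_point_sample(X, min(n_grid, X.shape[0]), seed)
    dens = kde_density(X, grid, n_localization=n_localization)
    glab, modes = mode_cluster(grid, dens, lambda_qs)
    return grid, dens, glab, modes


def bootstrap_stability(points: np.ndarray, ref_labels: np.ndarray,
                        n_grid: int, n_boot: int = 73, seed: int = 0,
                        lambda_qs: float = 3.0, n_localization: int | None = None,
                        mode_points: np.ndarray | None = None,
                        proximity_eps: float = 1e-3):
    """Bootstrap confusion of the reference microclusters.

    For each of ``n_boot`` seeded resamples (with replacement, size N) the
    clustering is re-run and every original point is assigned to a resampled
    cluster.  For reference clusters a, b the per-resample co-assignment is
    the overlap sum_c min(n_ac / n_a, n_bc / n_b) of their distributions over
    resampled clusters; the stability matrix averages this over resamples
    (diagonal 1 by construction).  A degenerate resample with a single
    cluster counts as merging every pair.

    Returns (stability, merge_tree) with the merge tree in scipy linkage
    format from average linkage on (1 - stability).  When ``mode_points``
    is given, a proximity term ``proximity_eps *`` (normalized mode-mode
    distance) is added to the dissimilarity: it is too small to override any
    real bootstrap confusion, but resolves the merge order among pairs of
    perfectly stable (never confused) microclusters by structural adjacency.
    """
    X = np.asarray(points, dtype=float)
    N = X.shape[0]
    ref = np.asarray(ref_labels, dtype=int)
    C = int(ref.max()) + 1
    n_a = np.bincount(ref, minlength=C).astype(float)
    rng = np.random.default_rng(seed)
    stab = np.zeros((C, C))
    for b in range(n_boot):
        idx = rng.integers(0, N, size=N)
        Xb = X[idx]
        sub_seed = int(rng.integers(2 ** 31 - 1))
        grid_b, dens_b, glab_b, _ = _cluster_once(Xb, n_grid, sub_seed,
                                                  lambda_qs, n_localization)
        lab_b = assign_microstates(X, grid_b, glab_b)
        Cb = int(glab_b.max()) + 1
        if Cb == 1:
            logger.info("bootstrap resample %d collapsed to one cluster", b)
            stab += 1.0
            continue
        conf = np.zeros((C, Cb))
        np.add.at(conf, (ref, lab_b), 1.0)
        frac = conf / n_a[:, None]
        stab += np.minimum(frac[:, None, :], frac[None, :, :]).sum(axis=2)
    stab /= n_boot
    stab = 0.5 * (stab + stab.T)
    np.fill_diagonal(stab, 1.0)
    if C > 1:
        dist = 1.0 - stab
        if mode_points is not None and len(mode_points) == C:
            md = np.linalg.norm(mode_points[:, None, :] - mode_points[None, :, :], axis=2)
            if md.max() > 0:
                dist = dist + proximity_eps * md / md.max()
        np.fill_diagonal(dist, 0.0)
        tree = linkage(squareform(dist, checks=False), method="average")
    else:
        tree = np.empty((0, 4))
    return stab, tree


def cut_macroclusters(merge_tree: np.ndarray, K: int) -> MacroMap:
    """Cut the microcluster dendrogram into exactly K macroclusters.

    Macrocluster ids are renumbered deterministically by the smallest
    microcluster index they contain.
    """
    C = merge_tree.shape[0] + 1
    if not (1 <= K <= C):
        raise ValueError(f"cannot cut {C} microclusters into K={K} groups")
    if K == C:
        raw = np.arange(C)
    else:
        raw = fcluster(merge_tree, t=K, criterion="maxclust") - 1
        if raw.max() + 1 != K:
            # tied heights can over-merge; fall back to cutting by merge order
            raw = fcluster(merge_tree, t=merge_tree[C - 1 - K, 2], criterion="distance") - 1
    # renumber by first occurrence
    remap = {}
    out = np.empty(C, dtype=int)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap)
        out[i] = remap[r]
    return MacroMap(micro_to_macro=out, K=int(out.max()) + 1)


def fit_microclusters(points: np.ndarray, n_grid: int | None = None,
                      seed: int = 0, lambda_qs: float = 3.0,
                      n_boot: int = 73, n_localization: int | None = None,
                      bootstrap: bool = True) -> MicroclusterModel:
    """Full microcluster pipeline: FPS grid, KDE, quick-shift, bootstrap."""
    X = np.asarray(points, dtype=float)
    N = X.shape[0]
    if n_grid is None:
        n_grid = int(min(1000, max(X.shape[1] + 1, N // 5)))
    grid, dens, glab, modes = _cluster_once(X, n_grid, seed, lambda_qs, n_localization)
    plab = assign_microstates(X, grid, glab)
    model = MicroclusterModel(grid=grid, density=dens, grid_labels=glab,
                              modes=grid.indices[modes], point_labels=plab)
    if bootstrap:
        stab, tree = bootstrap_stability(X, plab, n_grid=n_grid, n_boot=n_boot,
                                         seed=seed + 1, lambda_qs=lambda_qs,
                                         n_localization=n_localization,
                                         mode_points=X[model.modes])
        model.stability, model.merge_tree = stab, tree
    return model
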