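"""Dimensionality reduction and clustering of fight signatures.

Summary fight metrics go through PCA (eigendecomposition of the correlation
structure of the z-scored metric matrix); DTW dissimilarity matrices go
through classical PCoA (double-centering + eigendecomposition, negative
eigenvalues dropped).  The first three dimensions are retained from either
ordination.  Reduced scores are clustered by Ward agglomeration in the
un-squared Lance-Williams convention, and the number of clusters is chosen
by the gap statistic with a bootstrap uniform reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import (
    DegenerateGeometryError,
    ParameterError,
    SizeError,
)
from .dtw import DissimilarityMatrix

RETAINED_DIMS = 3


@dataclass
class OrdinationResult:
    """Scores and eigen-structure of one ordination (PCA or PCoA)."""

    ids: list[str]
    scores: np.ndarray  # fish x retained dimensions (Dim1..Dim3)
    eigenvalues: np.ndarray  # non-increasing; positive part for PCoA
    variance_explained: np.ndarray  # fraction per retained dimension
    cumulative_variance_dim1_3: float
    method: str  # "pca" | "pcoa"
    all_scores: Optional[np.ndarray] = None
    loadings: Optional[np.ndarray] = None
    columns: Optional[list[str]] = None

    @property
    def n_dims(self) -> int:
        return self.scores.shape[1]

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores,
            index=self.ids,
            columns=[f"Dim{i + 1}" for i in range(self.n_dims)],
        )


@dataclass
class ClusterResult:
    """A Ward merge tree plus flat labels at the chosen cluster count."""

    ids: list[str]
    merge_tree: list[tuple[int, int, float]]  # (left, right, height), scipy-style ids
    labels_at_k: np.ndarray
    k: int


@dataclass
class GapProfile:
    """Gap-statistic profile over candidate cluster numbers."""

    k_values: np.ndarray
    log_w: np.ndarray
    gap: np.ndarray
    se: np.ndarray
    chosen_k: int = field(default=1)


def pca(matrix: pd.DataFrame) -> OrdinationResult:
    """PCA of the z-scored fight-metric matrix.

    A ``fight_duration`` side column, if present, is excluded from the input.
    Components follow the sign convention that the largest-magnitude loading
    of each component is positive.
    """
    cols = [c for c in matrix.columns if c != "fight_duration"]
    X = matrix[cols].to_numpy(dtype=float)
    n = X.shape[0]
    if n < 3:
        raise SizeError(f"pca needs >= 3 fish, got {n}")
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    for j in range(eigvec.shape[1]):
        if eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    scores = Xc @ eigvec
    total = eigval.sum()
    frac = eigval / total if total > 0 else np.zeros_like(eigval)
    k = min(RETAINED_DIMS, int(np.sum(eigval > 1e-12 * max(total, 1.0))))
    return OrdinationResult(
        ids=[str(i) for i in matrix.index],
        scores=scores[:, :k],
        eigenvalues=eigval,
        variance_explained=frac[:k],
        cumulative_variance_dim1_3=float(frac[:k].sum()),
        method="pca",
        all_scores=scores,
        loadings=eigvec,
        columns=cols,
    )


def pcoa(matrix: DissimilarityMatrix | np.ndarray) -> OrdinationResult:
    """Classical scaling of a dissimilarity matrix.

    Double-centers -D^2/2, eigendecomposes, and keeps coordinates for the
    positive eigenvalues only (no Lingoes/Cailliez correction); variance
    fractions are taken over the positive eigenvalues.
    """
    if isinstance(matrix, DissimilarityMatrix):
        ids, D = matrix.ids, matrix.values
    else:
        D = np.asarray(matrix, dtype=float)
        ids = [str(i) for i in range(D.shape[0])]
    n = D.shape[0]
    if n < 3:
        raise SizeError(f"pcoa needs >= 3 fish, got {n}")
    if D.shape != (n, n) or np.max(np.abs(D - D.T)) > 1e-9:
        raise DegenerateGeometryError("pcoa input must be a symmetric square matrix")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = 1e-9 * max(1.0, float(np.abs(eigval).max()))
    pos = eigval > tol
    if not np.any(pos):
        raise DegenerateGeometryError("no positive eigenvalues; matrix has no embedding")
    lam = eigval[pos]
    coords = eigvec[:, pos] * np.sqrt(lam)
    frac = lam / lam.sum()
    k = min(RETAINED_DIMS, coords.shape[1])
    return OrdinationResult(
        ids=list(ids),
        scores=coords[:, :k],
        eigenvalues=lam,
        variance_explained=frac[:k],
        cumulative_variance_dim1_3=float(frac[:k].sum()),
        method="pcoa",
        all_scores=coords,
    )


def _as_distance_matrix(data) -> np.ndarray:
    """Accept a DissimilarityMatrix, a square symmetric matrix, or points."""
    if isinstance(data, DissimilarityMatrix):
        return np.asarray(data.values, dtype=float)
    arr = np.asarray(data, dtype=float)
    if (
        arr.ndim == 2
        and arr.shape[0] == arr.shape[1]
        and np.allclose(arr, arr.T, atol=1e-12)
        and np.allclose(np.diag(arr), 0.0, atol=1e-12)
    ):
        return arr
    return squareform(pdist(np.atleast_2d(arr)))


def ward_linkage(D: np.ndarray) -> list[tuple[int, int, float]]:
    """Ward agglomeration by the Lance-Williams update on the distances as-is.

    This is the un-squared convention (R's "ward.D"), distinct from the
    squared-distance variant: the update at each merge of clusters i, j is

        d(k, ij) = ((n_i + n_k) d(k, i) + (n_j + n_k) d(k, j) - n_k d(i, j))
                   / (n_i + n_j + n_k)

    Cluster ids follow the convention that originals are 0..n-1 and the m-th
    merge creates id n+m; ties merge the pair with the lexicographically
    smallest (left, right) ids.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise SizeError("ward_linkage needs >= 2 observations")
    total = 2 * n - 1
    M = np.full((total, total), np.inf)
    M[:n, :n] = D
    np.fill_diagonal(M, np.inf)
    sizes = np.zeros(total)
    sizes[:n] = 1
    active = np.zeros(total, dtype=bool)
    active[:n] = True
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        # row-major argmin over the symmetric matrix: for equal values the
        # (i, j) with i < j is seen first, giving the lexicographic tie-break
        flat = int(np.argmin(M))
        i, j = divmod(flat, total)
        if i > j:
            i, j = j, i
        d_ij = M[i, j]
        ni, nj = sizes[i], sizes[j]
        merges.append((int(i), int(j), float(d_ij)))
        new = n + step
        others = active.copy()
        others[[i, j]] = False
        nk = sizes[others]
        d_new = ((ni + nk) * M[i, others] + (nj + nk) * M[j, others] - nk * d_ij) / (
            ni + nj + nk
        )
        M[i, :] = M[:, i] = np.inf
        M[j, :] = M[:, j] = np.inf
        M[new, others] = d_new
        M[others, new] = d_new
        sizes[new] = ni + nj
        active[[i, j]] = False
        active[new] = True
    return merges


def cut_tree(merges: Sequence[tuple[int, int, float]], n: int, k: int) -> np.ndarray:
    """Flat labels from the first n - k merges; labels 0..k-1 ordered by the
    smallest original index in each cluster."""
    if not 1 <= k <= n:
        raise ParameterError(f"k must be in [1, {n}], got {k}")
    parent = list(range(n + len(merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m, (i, j, _h) in enumerate(merges[: n - k]):
        root = n + m
        parent[find(i)] = root
        parent[find(j)] = root
    roots = [find(i) for i in range(n)]
    first_member: dict[int, int] = {}
    for i, r in enumerate(roots):
        first_member.setdefault(r, i)
    order = sorted(first_member, key=lambda r: first_member[r])
    relabel = {r: li for li, r in enumerate(order)}
    return np.array([relabel[r] for r in roots], dtype=int)


def ward_cluster(data, k: int) -> ClusterResult:
    """Ward clustering of points or a distance matrix, cut at k clusters."""
    D = _as_distance_matrix(data)
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ParameterError(f"k must be in [1, {n}], got {k}")
    merges = ward_linkage(D)
    labels = cut_tree(merges, n, k)
    ids = data.ids if isinstance(data, DissimilarityMatrix) else [str(i) for i in range(n)]
    return ClusterResult(ids=list(ids), merge_tree=merges, labels_at_k=labels, k=k)


def _pooled_within_dispersion(points: np.ndarray, labels: np.ndarray) -> float:
    """W = sum over clusters of (sum of pairwise squared distances) / (2 n_r)."""
    w = 0.0
    for lab in np.unique(labels):
        pts = points[labels == lab]
        if len(pts) < 2:
            continue
        w += np.sum(pdist(pts) ** 2) / (2 * len(pts))
    return w


def gap_statistic(
    points,
    k_max: int,
    B: int = 100,
    seed: Optional[int] = None,
) -> GapProfile:
    """Gap statistic for the Ward clustering of score-space points.

    For each k in 1..k_max, the observed log pooled within-cluster dispersion
    log W_k is compared with its mean over B reference datasets drawn
    uniformly over each feature's observed range; se(k) is the bootstrap SD
    times sqrt(1 + 1/B).  The chosen k is filled in by :func:`choose_k`.
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    n = X.shape[0]
    if n < 3:
        raise SizeError(f"gap_statistic needs >= 3 points, got {n}")
    if k_max < 1:
        raise ParameterError(f"k_max must be >= 1, got {k_max}")
    if k_max > n - 1:
        raise ParameterError(f"k_max must be <= n - 1 = {n - 1}, got {k_max}")
    rng = np.random.default_rng(seed)
    ks = np.arange(1, k_max + 1)

    def profile(points_: np.ndarray) -> np.ndarray:
        merges = ward_linkage(_as_distance_matrix(points_))
        return np.array(
            [
                np.log(_pooled_within_dispersion(points_, cut_tree(merges, n, k)))
                for k in ks
            ]
        )

    log_w = profile(X)
    lo, hi = X.min(axis=0), X.max(axis=0)
    log_w_star = np.empty((B, k_max))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=X.shape)
        log_w_star[b] = profile(ref)
    gap = log_w_star.mean(axis=0) - log_w
    se = log_w_star.std(axis=0, ddof=0) * np.sqrt(1 + 1.0 / B)
    prof = GapProfile(k_values=ks, log_w=log_w, gap=gap, se=se)
    prof.chosen_k = choose_k(prof)
    return prof


def choose_k(profile: GapProfile) -> int:
    """Smallest k with gap(k) >= gap(k+1) - se(k+1); argmax-gap fallback.

    chosen_k = 1 is a valid outcome, reported downstream as "no discrete
    clusters".
    """
    gap, se, ks = profile.gap, profile.se, profile.k_values
    if len(ks) == 0:
        raise ParameterError("empty gap profile")
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - se[i + 1]:
            return int(ks[i])
    if len(ks) == 1:
        return int(ks[0])
    return int(ks[np.argmax(gap)])
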