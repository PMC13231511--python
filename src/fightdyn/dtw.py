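"""Dynamic time warping alignment and pairwise dissimilarity matrices.

DTW aligns two fights of unequal duration by a monotone warping path that
minimizes cumulative local distance.  The recursion is the symmetric step
pattern with double-weighted diagonal moves:

    g(i, j) = min( g(i-1, j) + d(i, j),
                   g(i, j-1) + d(i, j),
                   g(i-1, j-1) + 2 d(i, j) ),   g(1, 1) = d(1, 1)

with local distance d = |a_i - b_j| for univariate series and the Euclidean
norm of the 3-vector difference for multivariate ones.  No windowing
constraint is applied: fights are short (tens of samples), so the full O(NM)
table is cheap.  Both the unnormalized cumulative cost ("distance") and the
length-normalized cost distance/(N+M) are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .errors import FightDynError, PairingError, SizeError
from .io import CaptureDataset
from .preprocess import ProcessedSeries, make_variant


@dataclass
class DtwResult:
    """One alignment: cumulative cost, its length-normalized form and a path."""

    distance: float
    normalized_distance: float
    path: list[tuple[int, int]]


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise DTW distances for one processing variant."""

    ids: list[str]
    values: np.ndarray
    variant: Optional[tuple[str, str]] = None
    normalized_values: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def _local_cost(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    if a.ndim == 1:
        return np.abs(a[:, None] - b[None, :])
    return cdist(a, b)


def dtw_align(a: ProcessedSeries, b: ProcessedSeries) -> DtwResult:
    """Align two processed series sharing a (variant, channels) tag.

    Returns the unnormalized distance, the distance normalized by N + M and
    one optimal path.  Path tie-breaks prefer the diagonal step, then the
    step consuming series ``a``.
    """
    if (a.variant, a.channels) != (b.variant, b.channels):
        raise PairingError(
            f"cannot align {(a.variant, a.channels)} with {(b.variant, b.channels)}"
        )
    return dtw_align_arrays(a.values, b.values)


def dtw_align_arrays(x, y) -> DtwResult:
    """DTW on raw arrays (1-D, or 2-D with matching component count)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] == 0 or y.shape[0] == 0:
        raise SizeError("cannot align an empty series")
    d = _local_cost(x, y)
    n, m = d.shape
    g = np.empty((n, m))
    g[0, 0] = d[0, 0]
    for j in range(1, m):
        g[0, j] = g[0, j - 1] + d[0, j]
    for i in range(1, n):
        gi, gp, di = g[i], g[i - 1], d[i]
        gi[0] = gp[0] + di[0]
        for j in range(1, m):
            gi[j] = min(gp[j] + di[j], gi[j - 1] + di[j], gp[j - 1] + 2 * di[j])
    # backtrack; ties prefer diagonal, then the step consuming x
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            here = g[i, j]
            if np.isclose(g[i - 1, j - 1] + 2 * d[i, j], here):
                i, j = i - 1, j - 1
            elif np.isclose(g[i - 1, j] + d[i, j], here):
                i -= 1
            else:
                j -= 1
        path.append((i, j))
    path.reverse()
    dist = float(g[n - 1, m - 1])
    return DtwResult(distance=dist, normalized_distance=dist / (n + m), path=path)


def pairwise_dissimilarity(
    dataset: CaptureDataset,
    variant: str,
    channels: str,
    normalized: bool = False,
) -> DissimilarityMatrix:
    """DTW dissimilarity matrix over all fish pairs for one processing variant.

    n(n-1)/2 alignments; the matrix stores the unnormalized distance by
    default (``normalized=True`` stores distance/(N+M) instead); the other
    scale is kept alongside in ``normalized_values``.
    """
    ids = dataset.fish_ids
    if len(ids) < 2:
        raise SizeError("pairwise dissimilarity needs >= 2 fish")
    series = {fid: make_variant(dataset.traces[fid], variant, channels) for fid in ids}
    n = len(ids)
    raw = np.zeros((n, n))
    norm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                res = dtw_align(series[ids[i]], series[ids[j]])
            except FightDynError as exc:
                raise type(exc)(
                    f"alignment failed for pair ({ids[i]}, {ids[j]}): {exc}"
                ) from exc
            raw[i, j] = raw[j, i] = res.distance
            norm[i, j] = norm[j, i] = res.normalized_distance
    primary, secondary = (norm, raw) if normalized else (raw, norm)
    return DissimilarityMatrix(
        ids=ids, values=primary, variant=(variant, channels), normalized_values=secondary
    )
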