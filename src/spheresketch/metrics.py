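"""Cell-to-cell distances under the four supported metrics.

Supported metrics: ``euclidean``, ``manhattan``, ``cosine`` and ``pearson``
(one minus the Pearson correlation of the two coordinate rows).  Cosine and
Pearson distances are dissimilarities, not true metrics — nothing downstream
relies on the triangle inequality for them.

Balls are closed: a cell at distance exactly ``radius`` from a center is
covered.  Distances are computed in double precision and compared with
``<=`` directly, no epsilon slack.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

METRICS = ("euclidean", "manhattan", "cosine", "pearson")

# scipy spellings for the supported metric names
_SCIPY_NAME = {
    "euclidean": "euclidean",
    "manhattan": "cityblock",
    "cosine": "cosine",
    "pearson": "correlation",
}


class MetricError(ValueError):
    """A metric precondition is violated (bad name or degenerate row)."""


def _cell_name(cell_ids, i: int) -> str:
    return cell_ids[i] if cell_ids is not None else f"row {i}"


def check_metric(coords: np.ndarray, metric: str, cell_ids=None) -> None:
    """Validate that `metric` is supported and defined on every row.

    cosine requires nonzero row norms; pearson requires nonzero row variance
    and at least 2 dimensions (correlation of a scalar is undefined).
    """
    if metric not in METRICS:
        raise MetricError(f"unknown metric {metric!r}; choose from {METRICS}")
    coords = np.asarray(coords, dtype=np.float64)
    if metric == "cosine":
        norms = np.linalg.norm(coords, axis=1)
        bad = np.flatnonzero(norms == 0.0)
        if bad.size:
            raise MetricError(
                f"cosine distance undefined for zero-norm cell {_cell_name(cell_ids, bad[0])}"
            )
    elif metric == "pearson":
        if coords.shape[1] < 2:
            raise MetricError("pearson distance undefined for 1-dimensional coordinates")
        var = coords.var(axis=1)
        bad = np.flatnonzero(var == 0.0)
        if bad.size:
            raise MetricError(
                f"pearson distance undefined for zero-variance cell {_cell_name(cell_ids, bad[0])}"
            )


def pairwise_distances(points, metric: str = "euclidean") -> np.ndarray:
    """Symmetric ``n x n`` matrix of distances between all cells.

    The diagonal is exactly zero and tiny negative values produced by
    floating-point cancellation (cosine/pearson) are clipped to zero.
    """
    coords = np.asarray(getattr(points, "coords", points), dtype=np.float64)
    cell_ids = getattr(points, "cell_ids", None)
    check_metric(coords, metric, cell_ids)
    if coords.shape[0] == 1:
        return np.zeros((1, 1))
    dist = cdist(coords, coords, metric=_SCIPY_NAME[metric])
    dist += dist.T  # enforce exact symmetry
    dist *= 0.5
    np.maximum(dist, 0.0, out=dist)
    np.fill_diagonal(dist, 0.0)
    return dist


def cross_distances(a: np.ndarray, b: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Distances from each row of `a` to each row of `b` (shape ``len(a) x len(b)``)."""
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    check_metric(a, metric)
    check_metric(b, metric)
    dist = cdist(a, b, metric=_SCIPY_NAME[metric])
    np.maximum(dist, 0.0, out=dist)
    return dist


def ball_members(dist_row: np.ndarray, radius: float) -> np.ndarray:
    """Indices of all cells within the closed ball of `radius` around a center.

    `dist_row` is one row of a pairwise distance matrix; the center itself is
    always a member since its own distance is zero.
    """
    if radius < 0:
        raise ValueError(f"radius must be nonnegative, got {radius}")
    return np.flatnonzero(np.asarray(dist_row) <= radius)
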