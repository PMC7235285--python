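"""The in-memory container for a cell embedding.

A :class:`PointCloud` holds an ``n_cells x n_dims`` coordinate matrix
(typically PCA scores or another low-dimensional embedding) together with
one identifier per cell.  All downstream machinery — distance computation,
covering, sketching, evaluation — consumes this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class PointCloud:
    """An ``n x d`` numeric embedding of cells.

    Parameters
    ----------
    coords
        Real-valued matrix with cells as rows (``n >= 1``) and embedding
        dimensions as columns (``d >= 1``).  Must be finite throughout.
    cell_ids
        One unique identifier per cell.  If omitted, synthetic ids
        ``cell_0 .. cell_{n-1}`` are generated.
    """

    coords: np.ndarray
    cell_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=np.float64)
        if coords.ndim != 2:
            raise ValueError(f"coords must be 2-dimensional, got shape {coords.shape}")
        n, d = coords.shape
        if n < 1 or d < 1:
            raise ValueError(f"need at least 1 cell and 1 dimension, got {n} x {d}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords contain non-finite values")
        ids = tuple(self.cell_ids) if self.cell_ids else tuple(f"cell_{i}" for i in range(n))
        if len(ids) != n:
            raise ValueError(f"{len(ids)} cell_ids for {n} cells")
        if len(set(ids)) != n:
            raise ValueError("cell_ids are not unique")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "cell_ids", ids)

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]

    def subset(self, indices) -> "PointCloud":
        """Row-subset the cloud, keeping the matching cell ids."""
        idx = np.asarray(indices, dtype=np.intp)
        return PointCloud(self.coords[idx], tuple(self.cell_ids[i] for i in idx))
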