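"""Readers, writers and the default preprocessing pipeline.

Supported inputs: a dense numeric table (TSV/CSV, one cell per row or
column) holding an embedding such as PCA scores, or a sparse expression
matrix in Matrix Market triplet format with companion barcode/feature
files in the CellRanger dialect (genes as rows, cells as columns, 1-based
indices inside the MTX per that format's standard).

Raw counts can be passed through a documented default preprocessing —
per-cell total-count normalisation to the median total, ``log1p``, then
PCA — before sketching.  Users who already have an embedding select
``preprocessing="none"``.  All emitted indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import io as spio

from .cloud import PointCloud

FORMATS = ("dense_tsv", "dense_csv", "mtx")


@dataclass
class InputSpec:
    """Where and how to read the cell-by-feature matrix."""

    path: str
    format: str = "dense_tsv"
    orientation: str = "cells_as_rows"  # dense formats; mtx is genes x cells
    barcodes: str | None = None
    features: str | None = None
    preprocessing: str = "none"  # none | lognorm_pca
    n_components: int = 100

    def __post_init__(self) -> None:
        if self.format not in FORMATS:
            raise ValueError(f"unknown format {self.format!r}; choose from {FORMATS}")
        if self.orientation not in ("cells_as_rows", "cells_as_columns"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.preprocessing not in ("none", "lognorm_pca"):
            raise ValueError(f"unknown preprocessing {self.preprocessing!r}")
        if self.format == "mtx" and (self.barcodes is None or self.features is None):
            raise ValueError("mtx input requires companion barcodes and features files")


def _read_dense(path: str, sep: str) -> np.ndarray:
    table = pd.read_csv(path, sep=sep, header=None, float_precision="round_trip")
    try:
        return table.to_numpy(dtype=np.float64)
    except (TypeError, ValueError):
        for i, row in enumerate(table.itertuples(index=False), start=1):
            for value in row:
                try:
                    float(value)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric value {value!r} at line {i} of {path}"
                    ) from None
        raise


def _read_lines(path: str) -> list:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip() != ""]


def read_labels(path: str, n: int | None = None) -> list:
    labels = _read_lines(path)
    if n is not None and len(labels) != n:
        raise ValueError(f"{len(labels)} labels in {path} for {n} cells")
    return labels


def read_matrix(spec: InputSpec) -> PointCloud:
    """Load the matrix as a cells-as-rows :class:`PointCloud`.

    MTX files are read as coordinate triplets (1-based indices per the
    Matrix Market standard, handled by scipy) and densified; barcodes name
    the cells, and synthetic ids are generated for dense inputs.
    """
    if spec.format in ("dense_tsv", "dense_csv"):
        sep = "\t" if spec.format == "dense_tsv" else ","
        mat = _read_dense(spec.path, sep)
        if spec.orientation == "cells_as_columns":
            mat = mat.T
        cell_ids: tuple = ()
    else:
        sparse_mat = spio.mmread(spec.path)
        mat = np.asarray(sparse_mat.todense(), dtype=np.float64)
        if spec.orientation == "cells_as_columns":  # CellRanger: genes x cells on disk
            mat = mat.T
        barcodes = _read_lines(spec.barcodes)
        features = _read_lines(spec.features)
        if len(barcodes) != mat.shape[0]:
            raise ValueError(
                f"{len(barcodes)} barcodes for a matrix with {mat.shape[0]} cells"
            )
        if len(features) != mat.shape[1]:
            raise ValueError(
                f"{len(features)} features for a matrix with {mat.shape[1]} features"
            )
        cell_ids = tuple(barcodes)
    cloud = PointCloud(mat, cell_ids)
    if spec.preprocessing == "lognorm_pca":
        cloud = preprocess_lognorm_pca(cloud, spec.n_components)
    return cloud


def preprocess_lognorm_pca(raw: PointCloud, n_components: int = 100) -> PointCloud:
    """Median total-count normalisation, ``log1p``, PCA.

    The number of components is capped at ``min(n_cells, n_features)``.
    PCA signs follow a deterministic convention: the largest-magnitude
    loading of each component is made positive.
    """
    from sklearn.decomposition import PCA

    counts = raw.coords
    if (counts < 0).any():
        raise ValueError("lognorm_pca expects nonnegative entries")
    totals = counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cell {raw.cell_ids[zero[0]]} has zero total count")
    target = np.median(totals)
    norm = np.log1p(counts * (target / totals)[:, None])
    k = min(int(n_components), raw.n_cells, raw.n_dims)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(norm)
    for j in range(k):  # deterministic sign convention
        lead = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, lead] < 0:
            scores[:, j] *= -1.0
    return PointCloud(scores, raw.cell_ids)


def write_dense(path: str, cloud: PointCloud, sep: str = "\t") -> None:
    np.savetxt(path, cloud.coords, delimiter=sep, fmt="%.17g")


def write_indices(path: str, indices) -> None:
    with open(path, "w") as fh:
        fh.writelines(f"{int(i)}\n" for i in indices)


def read_indices(path: str) -> np.ndarray:
    values = _read_lines(path)
    return np.array([int(v) for v in values], dtype=np.intp)
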