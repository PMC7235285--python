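"""Sketch quality measures.

The headline measure is the robust (trimmed) directed Hausdorff distance
from the full data to the sketch: for every cell take its distance to the
nearest sketch cell, discard the largest ``floor(alpha * n)`` of those
values, and return the maximum of the remainder.  ``alpha = 0`` is the
exact directed Hausdorff distance; the default trim of 1% makes the
measure robust to a few stray cells.  Only the full-to-sketch direction is
meaningful here because the sketch is a subset of the data (the reverse
direction is identically zero).

:func:`composition_report` summarises how the sketch re-weights cell
classes — the lens for rare-population retention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import cross_distances


@dataclass
class HausdorffParams:
    """trim_fraction alpha in [0, 0.5): share of largest distances dropped."""

    trim_fraction: float = 0.01
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError(f"trim_fraction must be in [0, 0.5), got {self.trim_fraction}")


def nearest_sketch_distances(full, sketch_indices, metric: str = "euclidean") -> np.ndarray:
    """Per-cell distance to the nearest sketch cell."""
    idx = np.asarray(sketch_indices, dtype=np.intp)
    if idx.size == 0:
        raise ValueError("sketch is empty")
    coords = full.coords
    if idx.min() < 0 or idx.max() >= coords.shape[0]:
        raise IndexError("sketch index out of range")
    # chunk rows to keep the cross-distance block small on large inputs
    out = np.empty(coords.shape[0])
    step = max(1, 2_000_000 // max(1, idx.size))
    for start in range(0, coords.shape[0], step):
        block = coords[start: start + step]
        out[start: start + step] = cross_distances(block, coords[idx], metric).min(axis=1)
    out[idx] = 0.0
    return out


def robust_hausdorff(full, sketch_indices, params: HausdorffParams | None = None) -> float:
    """Trimmed directed Hausdorff distance from the full data to the sketch."""
    params = params or HausdorffParams()
    mind = nearest_sketch_distances(full, sketch_indices, params.metric)
    n = mind.size
    drop = math.floor(params.trim_fraction * n)
    if drop == 0:
        return float(mind.max())
    keep = n - drop
    return float(np.partition(mind, keep - 1)[keep - 1])


def composition_report(labels, sketch_indices) -> pd.DataFrame:
    """Class-by-class counts and fractions in the full data vs the sketch.

    Classes absent from the sketch are reported with a zero count, not
    dropped — that absence is usually the finding.
    """
    labels = list(labels)
    n = len(labels)
    idx = np.asarray(sketch_indices, dtype=np.intp)
    if idx.size and (idx.min() < 0 or idx.max() >= n):
        raise IndexError("sketch index out of range")
    full = pd.Series(labels).value_counts()
    sk = pd.Series([labels[i] for i in idx]).value_counts()
    table = pd.DataFrame({
        "full_count": full,
        "sketch_count": sk.reindex(full.index, fill_value=0),
    })
    table["full_fraction"] = table["full_count"] / table["full_count"].sum()
    table["sketch_fraction"] = table["sketch_count"] / max(1, table["sketch_count"].sum())
    table.index.name = "class"
    return table


def write_report(path_prefix: str, summary: dict, composition: pd.DataFrame | None = None) -> None:
    """Machine-readable outputs: <prefix>.summary.json and <prefix>.composition.tsv."""
    with open(f"{path_prefix}.summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if composition is not None:
        composition.to_csv(f"{path_prefix}.composition.tsv", sep="\t")
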