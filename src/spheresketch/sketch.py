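"""Minimum-radius spherical sketching.

A sketch of size ``k`` represents the data well if every cell lies within a
small radius of some sketch cell.  The bottleneck objective — minimise the
covering radius subject to at most ``k`` centers — is solved by the
thresholding technique: binary-search a candidate radius and test
feasibility with a greedy set cover ("does a greedy cover with balls of
this radius use at most k centers?").

Two radius searches are provided.  Ladder mode searches the sorted distinct
pairwise distances (the optimal radius is always one of them) and is the
default for moderate inputs.  Bisect mode bisects the continuous interval
``[0, max distance]`` to a relative tolerance and avoids sorting the
ladder, which for n cells holds ~n^2/2 values.

Greedy feasibility is not provably monotone along the ladder; the binary
search treats it as monotone, then verifies feasibility at the returned
radius and scans up to 32 ladder neighbours downward to tighten it.  This
is an approximation inherent to thresholding with a heuristic cover.

For large inputs, :func:`hybrid_sketch` first reduces the data with
:func:`grid_presample` (one representative per occupied hypercube of side
``s``), sketches the representatives, and measures the final radius on the
full data; each original cell shares a cube with its representative, so the
radius grows by at most ``s * sqrt(d)`` under the euclidean metric.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field, replace

import numpy as np

from .cloud import PointCloud
from .cover import CoverInstance, CoverParams, FairnessSpec, run_cover
from .metrics import cross_distances, pairwise_distances

#: above this many cells, "auto" radius mode switches from ladder to bisect
LADDER_MAX_CELLS = 20_000
#: ladder neighbours scanned downward after the binary search
LADDER_TIGHTEN_STEPS = 32


@dataclass
class SketchRequest:
    """What to sketch: target size, metric, engine and optional fairness.

    size may be an integer cell count or a fraction in (0, 1), resolved as
    ``ceil(fraction * n)``.
    """

    size: float
    metric: str = "pearson"
    fairness: FairnessSpec | None = None
    cover_params: CoverParams = field(default_factory=CoverParams)
    radius_mode: str = "auto"  # auto | ladder | bisect
    radius_tolerance: float = 1e-3
    pad_to_size: bool = False

    def __post_init__(self) -> None:
        if self.radius_mode not in ("auto", "ladder", "bisect"):
            raise ValueError(f"unknown radius_mode {self.radius_mode!r}")
        if self.radius_tolerance <= 0:
            raise ValueError("radius_tolerance must be positive")

    def resolve_size(self, n: int) -> int:
        size = self.size
        if isinstance(size, float) and 0 < size < 1:
            k = math.ceil(size * n)
        elif float(size).is_integer() and size >= 1:
            k = int(size)
        else:
            raise ValueError(f"sketch size must be a positive integer or fraction, got {size}")
        if k > n:
            raise ValueError(f"sketch size {k} exceeds number of cells {n}")
        return k


@dataclass
class Sketch:
    """Selected centers, the covering radius, and the per-cell assignment.

    ``radius`` is the covering threshold found by the search (direct mode)
    or the measured maximum assignment distance (hybrid mode);
    ``attained_radius`` is always the measured maximum distance of a cell to
    its assigned center, and never exceeds ``radius``.
    """

    center_indices: np.ndarray
    radius: float
    attained_radius: float
    assignment: np.ndarray
    metric: str
    grid_side: float | None = None

    @property
    def size(self) -> int:
        return len(self.center_indices)


@dataclass
class GridParams:
    """Hypercube presampling: give exactly one of target_size or side."""

    target_size: int | None = None
    side: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.target_size is None) == (self.side is None):
            raise ValueError("give exactly one of target_size or side")
        if self.side is not None and self.side <= 0:
            raise ValueError("grid side must be positive")
        if self.target_size is not None and self.target_size < 1:
            raise ValueError("grid target_size must be >= 1")


@dataclass
class GridSample:
    indices: np.ndarray
    side: float


def _assignment(dist_to_centers: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, float]:
    """Nearest-center assignment; each center is pinned to itself."""
    nearest = np.argmin(dist_to_centers, axis=1)
    assignment = centers[nearest]
    mindist = dist_to_centers[np.arange(dist_to_centers.shape[0]), nearest]
    assignment[centers] = centers  # duplicates at distance 0 must self-assign
    mindist = mindist.copy()
    mindist[centers] = 0.0
    return assignment, float(mindist.max())


def _pad_farthest(centers: list, dist: np.ndarray, k: int) -> list:
    """Top up to k centers with farthest-point additions (deterministic)."""
    centers = list(centers)
    chosen = np.zeros(dist.shape[0], dtype=bool)
    chosen[centers] = True
    mind = dist[:, centers].min(axis=1)
    while len(centers) < k and not chosen.all():
        mind[chosen] = -1.0
        nxt = int(np.argmax(mind))
        centers.append(nxt)
        chosen[nxt] = True
        np.minimum(mind, dist[:, nxt], out=mind)
    return centers


def min_radius_sketch(
    points: PointCloud, request: SketchRequest, timings: dict | None = None
) -> Sketch:
    """Smallest covering radius at which a greedy cover fits the size budget.

    Returns a :class:`Sketch` whose greedy cover at the returned radius has
    at most ``k`` centers while the feasibility test fails at the preceding
    candidate radius (ladder mode) or at ``radius * (1 - radius_tolerance)``
    (bisect mode).  If `timings` is a dict, wall-clock seconds for the
    distance and set-cover stages are accumulated into it.
    """
    n = points.n_cells
    k = request.resolve_size(n)
    fairness = request.fairness
    if fairness is not None:
        fairness.validate(n)
        if fairness.total_quota > k:
            raise ValueError(
                f"total fairness quota {fairness.total_quota} exceeds sketch size {k}"
            )
    tic = time.perf_counter()
    dist = pairwise_distances(points, request.metric)
    if timings is not None:
        timings["distances"] = timings.get("distances", 0.0) + time.perf_counter() - tic
    tic = time.perf_counter()

    cache: dict[float, list] = {}

    def cover_at(radius: float, probe: bool = False) -> list:
        # probe runs stop once the cover exceeds k; a probe result of size
        # <= k is a complete greedy run and is safe to reuse as the final
        # cover, so feasible radii are never recomputed
        if radius not in cache or (not probe and len(cache[radius]) > k):
            inst = CoverInstance.from_distances(dist, radius)
            cache[radius] = run_cover(
                inst, request.cover_params, fairness, max_size=k if probe else None
            )
        return cache[radius]

    def feasible(radius: float) -> bool:
        return len(cover_at(radius, probe=True)) <= k

    mode = request.radius_mode
    if mode == "auto":
        mode = "ladder" if n <= LADDER_MAX_CELLS else "bisect"

    if mode == "ladder":
        ladder = np.unique(dist)  # includes 0 from the diagonal

        def bisect_smallest(lo: int, hi: int) -> int:
            # smallest feasible index assuming monotone feasibility
            while lo < hi:
                mid = (lo + hi) // 2
                if feasible(float(ladder[mid])):
                    hi = mid
                else:
                    lo = mid + 1
            return hi

        # greedy feasibility is not provably monotone along the ladder: after
        # the monotone-assumption bisection, tighten by probing exponentially
        # spaced ladder indices below; any feasible probe restarts the
        # bisection beneath it.  The returned index is always feasible with
        # an infeasible immediate predecessor.
        idx = bisect_smallest(0, len(ladder) - 1)
        for _ in range(LADDER_TIGHTEN_STEPS):
            if idx == 0:
                break
            if feasible(float(ladder[idx - 1])):
                idx = bisect_smallest(0, idx - 1)
                continue
            found = None
            step = 2
            while idx - step > 0:
                if feasible(float(ladder[idx - step])):
                    found = idx - step
                    break
                step *= 2
            if found is None and idx > 1 and feasible(float(ladder[0])):
                found = 0
            if found is None:
                break
            idx = bisect_smallest(0, found)
        chosen = float(ladder[idx])
    else:
        max_dist = float(dist.max())
        if feasible(0.0):
            chosen = 0.0
        else:
            lo, hi = 0.0, max_dist
            tol = request.radius_tolerance
            for _ in range(200):
                if hi - lo <= tol * hi:
                    break
                mid = 0.5 * (lo + hi)
                if feasible(mid):
                    hi = mid
                else:
                    lo = mid
            chosen = hi

    centers = list(cover_at(chosen))
    if request.pad_to_size and len(centers) < k:
        centers = _pad_farthest(centers, dist, k)
    centers = np.asarray(centers, dtype=np.intp)
    if timings is not None:
        timings["set_cover"] = timings.get("set_cover", 0.0) + time.perf_counter() - tic
    assignment, attained = _assignment(dist[:, centers], centers)
    return Sketch(
        center_indices=centers,
        radius=chosen,
        attained_radius=attained,
        assignment=assignment,
        metric=request.metric,
    )


def _occupancy(coords: np.ndarray, origin: np.ndarray, side: float):
    keys = np.floor((coords - origin) / side).astype(np.int64)
    _, inverse = np.unique(keys, axis=0, return_inverse=True)
    return int(inverse.max()) + 1, inverse


def grid_presample(points: PointCloud, params: GridParams) -> GridSample:
    """One uniformly chosen cell per occupied axis-aligned hypercube.

    If ``target_size`` m is given, the side is found by bisection so that
    the number of occupied cubes lies in ``[m, 1.1 m]``, falling back to the
    closest achievable count; the grid is anchored at the coordinate-wise
    data minimum.
    """
    coords = points.coords
    n, d = coords.shape
    origin = coords.min(axis=0)
    extent = float((coords.max(axis=0) - origin).max())

    if params.side is not None:
        side = float(params.side)
        _, inverse = _occupancy(coords, origin, side)
    else:
        m = params.target_size
        if m > n:
            raise ValueError(f"grid target_size {m} exceeds number of cells {n}")
        if extent == 0.0:  # all cells identical: a single cube is all there is
            side = 1.0
            _, inverse = _occupancy(coords, origin, side)
        else:
            lo, hi = extent / 1e8, extent * (1 + 1e-9)
            best = None  # (|count - m|, prefer count >= m, side, inverse)
            side = None
            for _ in range(64):
                mid = math.sqrt(lo * hi)  # geometric bisection: side spans decades
                count, inv = _occupancy(coords, origin, mid)
                key = (abs(count - m), 0 if count >= m else 1)
                if best is None or key < best[0]:
                    best = (key, mid, inv)
                if m <= count <= 1.1 * m:
                    side, inverse = mid, inv
                    break
                if count < m:
                    hi = mid
                else:
                    lo = mid
            if side is None:
                _, side, inverse = best
        _, inverse = _occupancy(coords, origin, side)

    rng = np.random.default_rng(params.seed)
    order = np.argsort(inverse, kind="stable")
    starts = np.searchsorted(inverse[order], np.arange(int(inverse.max()) + 1))
    sizes = np.diff(np.append(starts, n))
    offsets = rng.integers(0, sizes)
    reps = np.sort(order[starts + offsets])
    return GridSample(indices=reps, side=float(side))


def hybrid_sketch(
    points: PointCloud, request: SketchRequest, grid: GridParams, timings: dict | None = None
) -> Sketch:
    """Grid presample, sketch the representatives, assign everyone.

    The reported radius is the maximum distance of any original cell to its
    assigned center — measured on the full data, not the representatives.
    """
    n = points.n_cells
    k = request.resolve_size(n)
    tic = time.perf_counter()
    sample = grid_presample(points, grid)
    if timings is not None:
        timings["grid"] = timings.get("grid", 0.0) + time.perf_counter() - tic
    if len(sample.indices) < k:
        raise ValueError(
            f"grid produced {len(sample.indices)} representatives, fewer than sketch size {k}"
        )
    sub = points.subset(sample.indices)
    sub_fairness = None
    if request.fairness is not None:
        sub_labels = [request.fairness.labels[i] for i in sample.indices]
        sub_fairness = FairnessSpec(labels=sub_labels, quotas=dict(request.fairness.quotas))
    sub_request = replace(request, size=float(k), fairness=sub_fairness)
    sub_sketch = min_radius_sketch(sub, sub_request, timings=timings)

    centers = sample.indices[sub_sketch.center_indices]
    dist_to_centers = cross_distances(points.coords, points.coords[centers], request.metric)
    assignment, attained = _assignment(dist_to_centers, centers)
    return Sketch(
        center_indices=centers,
        radius=attained,
        attained_radius=attained,
        assignment=assignment,
        metric=request.metric,
        grid_side=sample.side,
    )
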