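import math

import numpy as np
import pytest

from spheresketch.cloud import PointCloud
from spheresketch.cover import CoverInstance, CoverParams, FairnessSpec, run_cover
from spheresketch.metrics import pairwise_distances
from spheresketch.sketch import (
    GridParams,
    SketchRequest,
    grid_presample,
    hybrid_sketch,
    min_radius_sketch,
)

from conftest import brute_force_kcenter_radius, brute_force_min_cover_size, random_cloud


def greedy_cover_size_at(dist, radius, request):
    inst = CoverInstance.from_distances(dist, radius)
    return len(run_cover(inst, request.cover_params, request.fairness))


def assert_covering(points, sketch):
    dist = pairwise_distances(points, sketch.metric)
    assert np.all(dist[np.arange(points.n_cells), sketch.assignment] <= sketch.radius)
    assert sketch.attained_radius <= sketch.radius + 1e-12
    centers = sketch.center_indices
    assert len(set(centers.tolist())) == len(centers)
    assert np.array_equal(sketch.assignment[centers], centers)


def test_collinear_single_center():
    """5 points on a line, one sphere: the optimum is radius 2 at x=2."""
    points = PointCloud(np.arange(5.0)[:, None])
    sketch = min_radius_sketch(points, SketchRequest(size=1, metric="euclidean"))
    assert sketch.radius == pytest.approx(2.0)
    assert sketch.center_indices.tolist() == [2]
    assert_covering(points, sketch)


def test_k_equals_n_gives_radius_zero():
    points = PointCloud(np.random.default_rng(0).normal(size=(12, 3)))
    sketch = min_radius_sketch(points, SketchRequest(size=12, metric="euclidean"))
    assert sketch.radius == 0.0
    assert sorted(sketch.center_indices.tolist()) == list(range(12))
    assert np.array_equal(sketch.assignment, np.arange(12))


def test_two_identical_pairs_need_radius_zero():
    coords = np.array([[0.0, 0.0], [0.0, 0.0], [9.0, 9.0], [9.0, 9.0]])
    sketch = min_radius_sketch(PointCloud(coords), SketchRequest(size=2, metric="euclidean"))
    assert sketch.radius == 0.0
    picked = sorted(sketch.center_indices.tolist())
    assert len(picked) == 2 and picked[0] in (0, 1) and picked[1] in (2, 3)


def test_fraction_resolves_as_ceil():
    points = PointCloud(np.random.default_rng(1).normal(size=(213, 2)))
    request = SketchRequest(size=0.10, metric="euclidean")
    assert request.resolve_size(213) == 22  # ceil(21.3)
    assert request.resolve_size(2126) == 213


def test_size_validation():
    points = PointCloud(np.zeros((4, 2)) + np.arange(4)[:, None])
    with pytest.raises(ValueError, match="exceeds"):
        min_radius_sketch(points, SketchRequest(size=5, metric="euclidean"))
    fairness = FairnessSpec(["a", "a", "b", "b"], {"a": 2, "b": 2})
    with pytest.raises(ValueError, match="quota"):
        min_radius_sketch(
            points, SketchRequest(size=3, metric="euclidean", fairness=fairness)
        )


@pytest.mark.parametrize("metric", ["euclidean", "pearson"])
def test_ladder_feasibility_frontier(rng, metric):
    """The returned radius is feasible and the preceding ladder value is not."""
    for _ in range(25):
        n = int(rng.integers(8, 61))
        coords = random_cloud(rng, n, 4)
        k = int(rng.integers(1, max(2, n // 4)))
        request = SketchRequest(
            size=k, metric=metric, radius_mode="ladder",
            cover_params=CoverParams(seed=int(rng.integers(2**31))),
        )
        sketch = min_radius_sketch(PointCloud(coords), request)
        dist = pairwise_distances(coords, metric)
        ladder = np.unique(dist)
        idx = int(np.searchsorted(ladder, sketch.radius))
        assert ladder[idx] == sketch.radius
        assert greedy_cover_size_at(dist, sketch.radius, request) <= k
        if idx > 0:
            assert greedy_cover_size_at(dist, float(ladder[idx - 1]), request) > k


def test_bisect_mode_frontier(rng):
    """Bisect mode: feasible at the radius, infeasible a tolerance below."""
    for _ in range(5):
        coords = random_cloud(rng, 50, 3)
        request = SketchRequest(
            size=5, metric="euclidean", radius_mode="bisect", radius_tolerance=1e-3
        )
        sketch = min_radius_sketch(PointCloud(coords), request)
        dist = pairwise_distances(coords, "euclidean")
        assert greedy_cover_size_at(dist, sketch.radius, request) <= 5
        if sketch.radius > 0:
            below = sketch.radius * (1 - request.radius_tolerance)
            assert greedy_cover_size_at(dist, below, request) > 5


def test_bicriteria_near_optimality(rng):
    """On exhaustively solvable instances the radius is optimal whenever the
    greedy covers are optimal-size along the ladder; unconditionally it never
    beats the optimum for the reduced budget k / (1 + ln n)."""
    for _ in range(20):
        n = int(rng.integers(5, 11))
        coords = random_cloud(rng, n, 2)
        k = int(rng.integers(1, n))
        request = SketchRequest(size=k, metric="euclidean", radius_mode="ladder")
        sketch = min_radius_sketch(PointCloud(coords), request)
        dist = pairwise_distances(coords, "euclidean")
        opt_radius = brute_force_kcenter_radius(dist, k)

        greedy_always_optimal = all(
            greedy_cover_size_at(dist, float(r), request)
            == brute_force_min_cover_size(
                CoverInstance.from_distances(dist, float(r)).sets, n
            )
            for r in np.unique(dist)
        )
        if greedy_always_optimal:
            assert sketch.radius <= opt_radius + 1e-12
        reduced = max(1, math.floor(k / (1 + math.log(n))))
        assert sketch.radius <= brute_force_kcenter_radius(dist, reduced) + 1e-12


def test_radius_monotone_in_k(rng):
    coords = random_cloud(rng, 40, 3)
    radii = []
    for k in range(1, 12):
        sketch = min_radius_sketch(
            PointCloud(coords),
            SketchRequest(size=k, metric="euclidean", cover_params=CoverParams(seed=0)),
        )
        radii.append(sketch.radius)
    assert all(a >= b for a, b in zip(radii, radii[1:]))


def test_pad_to_size():
    points = PointCloud(np.arange(6.0)[:, None])
    request = SketchRequest(size=4, metric="euclidean", pad_to_size=True)
    sketch = min_radius_sketch(points, request)
    assert sketch.size == 4
    assert_covering(points, sketch)


def test_sketch_determinism(rng):
    coords = random_cloud(rng, 80, 4)
    request = SketchRequest(size=8, metric="euclidean", cover_params=CoverParams(seed=42))
    a = min_radius_sketch(PointCloud(coords), request)
    b = min_radius_sketch(PointCloud(coords), request)
    assert np.array_equal(a.center_indices, b.center_indices)
    assert a.radius == b.radius
    assert np.array_equal(a.assignment, b.assignment)


# ---------------------------------------------------------------- grid


def test_grid_single_cube_when_side_exceeds_extent(rng):
    points = PointCloud(rng.random((50, 3)))
    sample = grid_presample(points, GridParams(side=10.0))
    assert len(sample.indices) == 1


def test_grid_target_size_all_distinct(rng):
    points = PointCloud(rng.random((64, 2)))
    sample = grid_presample(points, GridParams(target_size=64))
    assert np.array_equal(sample.indices, np.arange(64))


def test_grid_two_separated_clusters(rng):
    coords = np.vstack([rng.normal(0, 0.5, (50, 2)), rng.normal(100, 0.5, (50, 2))])
    sample = grid_presample(PointCloud(coords), GridParams(side=2.0, seed=0))
    assert (sample.indices < 50).any() and (sample.indices >= 50).any()
    # every cell shares a cube with a representative: within side * sqrt(d)
    from spheresketch.metrics import cross_distances

    mind = cross_distances(coords, coords[sample.indices], "euclidean").min(axis=1)
    assert mind.max() <= 2.0 * math.sqrt(2) + 1e-12


def test_grid_parameter_validation(rng):
    with pytest.raises(ValueError, match="exactly one"):
        GridParams(target_size=5, side=1.0)
    with pytest.raises(ValueError, match="exactly one"):
        GridParams()
    points = PointCloud(rng.random((10, 2)))
    with pytest.raises(ValueError, match="exceeds"):
        grid_presample(points, GridParams(target_size=11))


# ---------------------------------------------------------------- hybrid


def test_hybrid_noop_grid_matches_direct(rng):
    coords = random_cloud(rng, 60, 3)
    points = PointCloud(coords)
    request = SketchRequest(size=6, metric="euclidean", cover_params=CoverParams(seed=5))
    direct = min_radius_sketch(points, request)
    hybrid = hybrid_sketch(points, request, GridParams(target_size=60, seed=5))
    assert np.array_equal(np.sort(hybrid.center_indices), np.sort(direct.center_indices))
    assert hybrid.radius == pytest.approx(direct.attained_radius, abs=1e-12)


def test_hybrid_inflation_bound(rng):
    """Hybrid radius exceeds the direct radius by at most side * sqrt(d)."""
    for _ in range(15):
        n = int(rng.integers(40, 200))
        d = int(rng.integers(2, 6))
        coords = random_cloud(rng, n, d)
        points = PointCloud(coords)
        k = int(rng.integers(2, max(3, n // 10)))
        request = SketchRequest(size=k, metric="euclidean", cover_params=CoverParams(seed=1))
        direct = min_radius_sketch(points, request)
        m = min(n, max(k, n // 2))
        hybrid = hybrid_sketch(points, request, GridParams(target_size=m, seed=1))
        assert hybrid.radius <= direct.radius + hybrid.grid_side * math.sqrt(d) + 1e-9


def test_hybrid_k_equals_m_radius_is_rep_distance(rng):
    coords = random_cloud(rng, 100, 3)
    points = PointCloud(coords)
    sample = grid_presample(points, GridParams(target_size=20, seed=3))
    m = len(sample.indices)
    request = SketchRequest(size=m, metric="euclidean")
    hybrid = hybrid_sketch(points, request, GridParams(target_size=20, seed=3))
    from spheresketch.metrics import cross_distances

    expected = cross_distances(coords, coords[sample.indices], "euclidean").min(axis=1).max()
    assert hybrid.radius == pytest.approx(float(expected), abs=1e-12)
    assert np.array_equal(np.sort(hybrid.center_indices), sample.indices)


def test_hybrid_requires_enough_representatives(rng):
    points = PointCloud(random_cloud(rng, 30, 2))
    request = SketchRequest(size=10, metric="euclidean")
    with pytest.raises(ValueError, match="fewer than sketch size"):
        hybrid_sketch(points, request, GridParams(target_size=5))
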