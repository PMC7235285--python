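"""Shared fixtures and independent brute-force oracles.

The oracles here (exhaustive minimum set cover, exhaustive k-center
radius, double-loop Hausdorff) deliberately share no code with the package
paths they check.
"""

from itertools import combinations

import numpy as np
import pytest

from spheresketch.cover import CoverInstance


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def brute_force_min_cover_size(sets, universe_size: int) -> int:
    """Smallest number of sets whose union is the universe (exhaustive)."""
    universe = frozenset(range(universe_size))
    as_sets = [frozenset(np.asarray(s).tolist()) for s in sets]
    for size in range(1, len(as_sets) + 1):
        for combo in combinations(range(len(as_sets)), size):
            union = frozenset().union(*(as_sets[i] for i in combo))
            if union >= universe:
                return size
    raise AssertionError("no subcollection covers the universe")


def brute_force_kcenter_radius(dist: np.ndarray, k: int) -> float:
    """Optimal k-center bottleneck radius by exhaustive center enumeration."""
    n = dist.shape[0]
    best = np.inf
    for combo in combinations(range(n), k):
        radius = dist[:, combo].min(axis=1).max()
        best = min(best, float(radius))
    return best


def brute_force_directed_hausdorff(full: np.ndarray, sketch: np.ndarray) -> float:
    """Double-loop directed Hausdorff (euclidean), independent of the package."""
    worst = 0.0
    for x in full:
        nearest = min(float(np.sqrt(((x - y) ** 2).sum())) for y in sketch)
        worst = max(worst, nearest)
    return worst


def random_cover_instance(rng: np.random.Generator, max_n: int = 12) -> CoverInstance:
    """Random set-cover instance where each element's own set contains it."""
    n = int(rng.integers(2, max_n + 1))
    sets = []
    for i in range(n):
        density = rng.uniform(0.05, 0.6)
        extra = np.flatnonzero(rng.random(n) < density)
        sets.append(np.union1d([i], extra))
    return CoverInstance(sets=sets, universe_size=n)


def greedy_trace(sets, universe_size: int):
    """Reference greedy (first-index tie-break); reports whether any step tied.

    On tie-free instances every tie-break policy gives the same selection,
    so the package engines must match this trace in size.
    """
    covered = set()
    selection = []
    tied = False
    remaining = set(range(len(sets)))
    while len(covered) < universe_size:
        residuals = {
            i: len(set(np.asarray(sets[i]).tolist()) - covered) for i in remaining
        }
        best = max(residuals.values())
        if best == 0:
            raise AssertionError("instance not coverable")
        winners = [i for i, r in residuals.items() if r == best]
        if len(winners) > 1:
            tied = True
        pick = min(winners)
        selection.append(pick)
        covered |= set(np.asarray(sets[pick]).tolist())
        remaining.discard(pick)
    return selection, tied


def random_cloud(rng: np.random.Generator, n: int, d: int) -> np.ndarray:
    """Clustered coordinates: a few Gaussian blobs, like a small embedding."""
    n_blobs = int(rng.integers(1, 5))
    centers = rng.normal(scale=6.0, size=(n_blobs, d))
    member = rng.integers(0, n_blobs, size=n)
    return centers[member] + rng.standard_normal((n, d))
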