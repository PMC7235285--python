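"""Fixed-radius minimum set cover by greedy selection.

Covering all cells with the fewest closed balls of a given radius is a set
cover problem: candidate set ``i`` is the set of cells within the radius of
cell ``i``.  Two engines are provided:

``exact_greedy``
    Textbook greedy: repeatedly select the candidate covering the most
    still-uncovered cells, achieving the classical ``1 + ln n``
    approximation.  Ties between equal residual sizes are broken uniformly
    at random from a seeded generator — the only random decision in the
    whole pipeline.

``dfg``
    The disk-friendly greedy: candidates are grouped into geometric buckets
    by residual size (bucket ``k`` holds sizes in ``[p^k, p^{k+1})``,
    ``p > 1``); buckets are processed from largest down, residual sizes are
    recomputed lazily only when a candidate is popped, and stale candidates
    are demoted to the bucket of their true residual size.  This trades an
    ``~p`` factor in cover size for strictly sequential access patterns and
    scales to very large inputs.  As ``p -> 1`` it degenerates to exact
    greedy.

Fairness quotas ("select at least ``c_j`` centers of class ``j``") are
expressed as covering requirements: conceptually the universe is augmented
with ``c_j`` virtual elements per class, and a selected center of class
``j`` absorbs one still-unmet virtual requirement of its class.
Concretely, every unselected candidate of a class with an unmet quota
carries a residual bonus of ``+1``.  The greedy cannot terminate before all
quotas are absorbed, so quota satisfaction is structural; with all quotas
zero the bonus vanishes and the engines reproduce the unconstrained output
bit for bit (same tie-break stream).
"""

from __future__ import annotations

import heapq
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .metrics import ball_members


@dataclass
class CoverParams:
    """Engine configuration.

    p : bucket base of the disk-friendly greedy, must be > 1.  Small values
        (default 1.05) give near-greedy cover quality.
    seed : seed for the tie-breaking / bucket-permutation RNG.
    engine : "exact_greedy" or "dfg".
    """

    p: float = 1.05
    seed: int = 0
    engine: str = "exact_greedy"

    def __post_init__(self) -> None:
        if self.engine not in ("exact_greedy", "dfg"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if self.engine == "dfg" and self.p <= 1:
            raise ValueError(f"DFG bucket base p must be > 1, got {self.p}")


@dataclass
class FairnessSpec:
    """Per-cell class labels and per-class minimum center quotas."""

    labels: list
    quotas: dict = field(default_factory=dict)

    def validate(self, n: int) -> None:
        if len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} cells")
        counts: dict = {}
        for lab in self.labels:
            counts[lab] = counts.get(lab, 0) + 1
        for cls, quota in self.quotas.items():
            if quota < 0:
                raise ValueError(f"negative quota for class {cls!r}")
            if cls not in counts:
                raise ValueError(f"quota class {cls!r} absent from labels")
            if quota > counts[cls]:
                raise ValueError(
                    f"quota {quota} for class {cls!r} exceeds its {counts[cls]} member cells"
                )

    @property
    def total_quota(self) -> int:
        return sum(self.quotas.values())


@dataclass
class CoverInstance:
    """Ball membership at a fixed radius: ``sets[i]`` = cells covered by cell ``i``."""

    sets: list
    universe_size: int
    radius: float = 0.0
    #: True when j in sets[i] iff i in sets[j] (ball membership from a
    #: symmetric distance matrix); lets the greedy reuse sets as its
    #: inverted index instead of building one.
    symmetric: bool = False

    def __post_init__(self) -> None:
        self.sets = [np.asarray(s, dtype=np.intp) for s in self.sets]

    @classmethod
    def from_distances(cls, dist: np.ndarray, radius: float) -> "CoverInstance":
        dist = np.asarray(dist)
        sets = [ball_members(dist[i], radius) for i in range(dist.shape[0])]
        return cls(sets=sets, universe_size=dist.shape[0], radius=radius, symmetric=True)

    def validate(self) -> None:
        hit = np.zeros(self.universe_size, dtype=bool)
        for i, s in enumerate(self.sets):
            if s.size and (s.min() < 0 or s.max() >= self.universe_size):
                raise ValueError(f"set {i} contains out-of-range elements")
            if i < self.universe_size and i not in s:
                raise ValueError(f"cell {i} does not cover itself")
            hit[s] = True
        if not hit.all():
            missing = int(np.flatnonzero(~hit)[0])
            raise ValueError(f"element {missing} is not covered by any set")


def _quota_state(n_sets: int, labels, quotas):
    """Remaining per-class quota and per-class candidate lists, or (None, None)."""
    if labels is None or not quotas:
        return None, None
    remaining = {cls: int(q) for cls, q in quotas.items() if q > 0}
    if not remaining:
        return None, None
    by_class: dict = {cls: [] for cls in remaining}
    for i in range(n_sets):
        if labels[i] in by_class:
            by_class[labels[i]].append(i)
    return remaining, {cls: np.asarray(ix, dtype=np.intp) for cls, ix in by_class.items()}


def exact_greedy_cover(
    instance: CoverInstance, seed: int = 0, labels=None, quotas=None, max_size: int | None = None
) -> list:
    """Greedy set cover; returns selected candidate indices in selection order.

    Each step selects a candidate of maximal residual coverage (uncovered
    cells in its ball, plus 1 if its class has an unmet quota); ties are
    broken uniformly at random by the seeded RNG.  `max_size` turns the run
    into a feasibility probe: selection stops as soon as the cover exceeds
    it (the partial result then only signals infeasibility).
    """
    sets = instance.sets
    n_sets = len(sets)
    universe = instance.universe_size
    rng = np.random.default_rng(seed)

    covered = np.zeros(universe, dtype=bool)
    n_uncov = universe
    counts = np.array([len(s) for s in sets], dtype=np.int64)

    # inverted index: owners of element j = candidates whose ball contains j;
    # for symmetric ball instances that is sets[j] itself
    if instance.symmetric:
        owners = sets
    else:
        lens = np.array([len(s) for s in sets], dtype=np.intp)
        all_elems = np.concatenate(sets) if n_sets else np.empty(0, dtype=np.intp)
        set_of_elem = np.repeat(np.arange(n_sets, dtype=np.intp), lens)
        order = np.argsort(all_elems, kind="stable")
        owners_flat = set_of_elem[order]
        bounds = np.searchsorted(all_elems[order], np.arange(universe + 1))
        owners = [owners_flat[bounds[j]: bounds[j + 1]] for j in range(universe)]

    remaining, by_class = _quota_state(n_sets, labels, quotas)
    if remaining:
        for cls in remaining:
            counts[by_class[cls]] += 1

    selected: list = []
    while n_uncov > 0 or (remaining and any(q > 0 for q in remaining.values())):
        if max_size is not None and len(selected) > max_size:
            return selected
        best = counts.max()
        if best <= 0:
            raise ValueError("cover infeasible: no candidate has positive residual coverage")
        cands = np.flatnonzero(counts == best)
        c = int(cands[rng.integers(len(cands))])
        selected.append(c)

        newly = sets[c][~covered[sets[c]]]
        if newly.size:
            covered[newly] = True
            n_uncov -= int(newly.size)
            dec = np.concatenate([owners[j] for j in newly])
            counts -= np.bincount(dec, minlength=n_sets)
        if remaining is not None and labels[c] in remaining and remaining[labels[c]] > 0:
            remaining[labels[c]] -= 1
            if remaining[labels[c]] == 0:
                counts[by_class[labels[c]]] -= 1  # retire the class bonus
        counts[c] = -1  # never reselect
    return selected


def _bucket_of(size: int, log_p: float) -> int:
    # consistent bucket index; small forward nudge guards against log rounding
    return int(math.floor(math.log(size) / log_p + 1e-12))


def dfg_cover(
    instance: CoverInstance, params: CoverParams, labels=None, quotas=None,
    max_size: int | None = None,
) -> list:
    """Disk-friendly greedy set cover (lazy bucketed residual evaluation).

    `max_size` turns the run into a feasibility probe, as in
    :func:`exact_greedy_cover`.
    """
    if params.p <= 1:
        raise ValueError(f"DFG bucket base p must be > 1, got {params.p}")
    sets = instance.sets
    n_sets = len(sets)
    universe = instance.universe_size
    rng = np.random.default_rng(params.seed)
    log_p = math.log(params.p)

    covered = np.zeros(universe, dtype=bool)
    n_uncov = universe
    remaining, _ = _quota_state(n_sets, labels, quotas)

    def bonus(i: int) -> int:
        return 1 if remaining and remaining.get(labels[i], 0) > 0 else 0

    buckets: dict = {}
    for i in rng.permutation(n_sets):  # within-bucket order: seeded permutation
        i = int(i)
        size = len(sets[i]) + bonus(i)
        k = _bucket_of(size, log_p)
        buckets.setdefault(k, deque()).append(i)
    heap = [-k for k in buckets]
    heapq.heapify(heap)

    selected: list = []
    quota_open = bool(remaining) and any(q > 0 for q in remaining.values())
    while n_uncov > 0 or quota_open:
        if max_size is not None and len(selected) > max_size:
            return selected
        if not heap:
            raise ValueError("cover infeasible: bucket queue exhausted with elements uncovered")
        k = -heapq.heappop(heap)
        bucket = buckets.get(k)
        if not bucket:
            continue
        i = bucket.popleft()
        if bucket:
            heapq.heappush(heap, -k)
        residual = int(np.count_nonzero(~covered[sets[i]])) + bonus(i)
        if residual == 0:
            continue
        kk = _bucket_of(residual, log_p)
        if kk == k:  # residual still current for this bucket: select
            newly = sets[i][~covered[sets[i]]]
            covered[newly] = True
            n_uncov -= int(newly.size)
            selected.append(i)
            if remaining is not None and labels[i] in remaining and remaining[labels[i]] > 0:
                remaining[labels[i]] -= 1
            quota_open = bool(remaining) and any(q > 0 for q in remaining.values())
        else:  # stale: demote to the bucket of its true residual size
            buckets.setdefault(kk, deque()).append(i)
            heapq.heappush(heap, -kk)
    return selected


def fair_greedy_cover(
    instance: CoverInstance, fairness: FairnessSpec, params: CoverParams
) -> list:
    """Greedy cover satisfying per-class center quotas.

    With all quotas zero this is identical (bit for bit, at fixed seed) to
    the unconstrained engine.
    """
    fairness.validate(len(instance.sets))
    if params.engine == "dfg":
        return dfg_cover(instance, params, labels=fairness.labels, quotas=fairness.quotas)
    return exact_greedy_cover(
        instance, seed=params.seed, labels=fairness.labels, quotas=fairness.quotas
    )


def run_cover(
    instance: CoverInstance,
    params: CoverParams,
    fairness: FairnessSpec | None = None,
    max_size: int | None = None,
) -> list:
    """Dispatch to the configured engine, with or without fairness."""
    labels = quotas = None
    if fairness is not None and fairness.quotas:
        fairness.validate(len(instance.sets))
        labels, quotas = fairness.labels, fairness.quotas
    if params.engine == "dfg":
        return dfg_cover(instance, params, labels=labels, quotas=quotas, max_size=max_size)
    return exact_greedy_cover(
        instance, seed=params.seed, labels=labels, quotas=quotas, max_size=max_size
    )
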