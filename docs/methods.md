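# Methods

## The model

Given an embedding of `n` cells (rows of an `n × d` matrix, typically PCA
scores) and a distance `d(·,·)` between cells, a *spherical sketch* of size
`k` is a set `S` of at most `k` cells such that every cell lies within a
radius `r` of some member of `S` — closed balls of radius `r` around the
sketch cells cover the data.  The objective is the bottleneck (k-center)
one: minimise `r` subject to `|S| ≤ k`.  Small `r` means every
transcriptomic state, including rare ones, has a nearby representative;
this is the property that makes a sketch useful for accelerating
clustering or trajectory inference without losing rare populations.

The optimisation is solved by the thresholding technique:

1. **Threshold search.** Binary-search a candidate radius `r`.
2. **Feasibility test.** At fixed `r`, covering all cells with the fewest
   balls is a set cover instance (candidate set `i` = cells within `r` of
   cell `i`).  Run greedy set cover; `r` is feasible if the cover uses at
   most `k` centers.
3. Return the smallest feasible radius; the greedy cover at that radius is
   the sketch.  Every cell is assigned to its nearest center.

Greedy set cover guarantees a cover within `1 + ln n` of the smallest one,
which yields the usual bicriteria reading: at the optimal radius the
greedy may use up to `(1 + ln n)·k` centers, equivalently with budget `k`
it finds the smallest radius whose optimal cover is roughly `k/(1+ln n)`.
The package asserts this unconditionally on exhaustively solvable
instances, and exact radius optimality whenever the greedy happens to be
optimal-size along the whole search.

### Radius candidates: ladder vs bisect

The optimal radius is always one of the `O(n²)` distinct pairwise
distances, so the default ("ladder") search bisects that sorted list and
is exact up to the feasibility test.  For large `n` the ladder itself is
the bottleneck (12.5M values at `n = 5000`), so a "bisect" mode bisects
the continuous interval `[0, max distance]` to a relative tolerance
(default `1e-3`): the returned radius is feasible while
`r·(1 − tolerance)` is not.  `auto` mode uses the ladder up to 20 000
cells.  The package's own large-scale studies (the `n = 5000` mixtures in
the acceptance script and test suite) use bisect mode, trading a ≤0.1%
radius slack for an order-of-magnitude faster search.

Greedy feasibility is not provably monotone in `r`.  The binary search
assumes monotonicity, then tightens: it verifies feasibility at the
returned ladder index, probes exponentially spaced ladder indices below
it, and restarts the bisection beneath any feasible probe (up to 32
rounds).  The returned radius is always feasible with an infeasible
immediate predecessor; in rare fragmented-feasibility instances it may
still sit above the true smallest feasible ladder value.  This is an
approximation inherent to thresholding with a heuristic cover, not a bug;
the simpler "stop at the first infeasible neighbour" scan was observed to
strand the radius tens of ladder steps too high on small clustered
instances, which is why the probing variant is used.

### Tie-breaking and determinism

The only random decision in the pipeline is breaking ties between
candidate sets of equal residual coverage; it is driven by one seeded
generator, so identical seeds give bitwise-identical sketches.  In the
disk-friendly greedy, the within-bucket processing order is a seeded
permutation.

## Cover engines

**Exact greedy** maintains residual coverage counts incrementally through
an inverted element→sets index (for ball instances the index is the sets
themselves, by symmetry of the distance matrix) and selects a maximal
residual candidate per step, uniformly at random among ties.

**Disk-friendly greedy (DFG)** buckets candidates by residual size into
geometric ranges `[p^k, p^{k+1})`, processes buckets from largest down,
recomputes a candidate's residual only when it is popped, and demotes
stale candidates to the bucket of their true residual.  This gives an
`≈ p·(1 + ln n)` cover-size guarantee while touching each candidate only
`O(log_p n)` times — the access pattern that scales to very large inputs.
Default `p = 1.05`; as `p → 1` the engine degenerates to exact greedy
(verified as a property test on tie-free instances — cover *sizes* under
ties legitimately depend on tie-break order).

Both engines accept a `max_size` cap so that a feasibility probe can stop
as soon as the cover exceeds the budget.

## Fairness quotas

A quota `c_j` requires at least `c_j` selected centers of class `j`
(e.g. a collection time point).  This is a covering constraint: the
universe is conceptually augmented with `c_j` virtual requirements per
class, and a selected center of class `j` absorbs at most one still-open
requirement of its own class (set multicover).  Concretely every
unselected candidate of a class with an open quota carries a `+1`
residual bonus.  Consequences, all structural:

- the greedy cannot terminate before all quotas are absorbed, and each
  selection absorbs at most one unit, so quota satisfaction is guaranteed;
- with all quotas zero the bonus vanishes and the engine reproduces the
  unconstrained run bit for bit (identical tie-break stream);
- cells whose label disagrees with their transcriptomic neighbourhood
  ("outliers" in a time course) are implicitly discouraged as centers:
  their quota is filled by genuine same-label cells in that label's own
  dense region, after which they compete without a bonus against
  better-covering candidates.

The shared-virtual-element alternative (each class-`j` candidate covering
all `c_j` virtual elements) was rejected: a single selection would absorb
the whole quota, so it cannot enforce `c_j > 1`.

## Grid presampling and the hybrid pipeline

`grid_presample` partitions the embedding into axis-aligned hypercubes of
side `s` anchored at the coordinate-wise minimum and keeps one uniformly
chosen cell per occupied cube.  Given a target count `m` instead of `s`,
the side is found by geometric bisection so the occupied-cube count lands
in `[m, 1.1m]` (closest achievable count as fallback).

`hybrid_sketch` presamples, runs the radius search on the representatives
only, then assigns *every* original cell to its nearest selected center
and reports the measured maximum assignment distance as the radius.  Each
cell shares a cube with its representative, so under the euclidean metric
the hybrid radius exceeds the direct one by roughly the cube diagonal
`s·√d`; the package asserts `hybrid ≤ direct + s·√d` as a stochastic
property over 500 clustered instances.  The bound is empirical, not a
theorem — the provable chain is `hybrid ≤ r_sub + s·√d` with
`r_sub ≤ direct + s·√d` only for optimal covers — and it is only
meaningful with substantially more representatives than centers (the CLI
defaults to `10·k`).  For cosine/pearson the grid still uses axis-aligned
boxes on the raw coordinates; the inflation bound is then heuristic.

A direct sketch reports the threshold radius found by the search
(`Sketch.radius`) alongside the measured maximum assignment distance
(`Sketch.attained_radius ≤ radius`); a hybrid sketch reports the measured
value for both, since the representative-level threshold does not bound
the full data.

## Distances

Four per-cell dissimilarities: euclidean, manhattan, cosine
(`1 − cosine similarity`) and pearson (`1 −` Pearson correlation of the
two coordinate rows; the package default, matching common practice for
expression embeddings).  Cosine and pearson are not metrics; nothing in
the search relies on the triangle inequality, and optimality-flavoured
properties are asserted for euclidean/manhattan only.  Balls are closed
(`≤ r`, no epsilon slack), so radius 0 is always feasible with `k = n`.
Degenerate rows (zero norm under cosine, zero variance or a single
dimension under pearson) are rejected with the offending cell named.
Distances are computed in double precision with `scipy.spatial.cdist`,
symmetrised, and clipped at zero.

## Evaluation

`robust_hausdorff` is the directed, trimmed Hausdorff distance from the
full data to the sketch: per-cell nearest-sketch distances, drop the
largest `floor(α·n)`, return the maximum.  Default `α = 0.01`; `α = 0` is
the exact directed Hausdorff distance and, for a sketch produced by the
radius search, never exceeds the reported radius.  Only the full→sketch
direction is computed because the sketch is a subset of the data.
`composition_report` tabulates per-class counts and fractions in the full
data versus the sketch, keeping zero-count classes.

## Synthetic data

The generator draws a Gaussian mixture in `d` dimensions: component
membership from the abundance weights, coordinates as component mean plus
isotropic noise.  The standard study mixture is `n = 5000` cells,
`d = 10`, five components at separation 8 with unit noise, one component
at 1% abundance — well-separated dominant clusters plus a small distant
one, i.e. the regime where uniform subsampling loses the rare population
and even sampling should not.  Labels are component names or the four
cycling time points `t0/t24/t48/t72` (a 72-hour course sampled daily);
`generate_outlier_timepoints` relabels a few dense-component cells with a
foreign time point to create planted label/state disagreements.

What the generator does *not* emulate: count noise (dropout, library
size), anisotropic or overlapping populations, batch structure, and the
preprocessing that produces real embeddings.  Passing tests therefore
demonstrate the combinatorial and geometric guarantees of the method, not
end-to-end performance on real scRNA-seq data; the `lognorm_pca`
preprocessing default (median total-count normalisation, `log1p`, PCA
with a deterministic sign convention) is a documented stand-in for
study-specific pipelines.

## Problem sizes and numerical choices

- Test-suite and acceptance-study sizes: covering invariants on up to 500
  cells across all metrics; exhaustive oracles up to 12 elements
  (set cover) and 10 cells (k-center); rare-retention and Hausdorff
  comparisons on the standard 5000-cell mixture with bisect-mode search
  and the DFG engine.  These sizes exercise every code path at scales
  where independent brute-force verification is possible.
- Ladder/bisect switch at 20 000 cells; bisect relative tolerance `1e-3`.
- DFG bucket index `floor(log(size)/log(p) + 1e-12)`; the nudge guards
  against log rounding at exact powers of `p`.
- Fractional sketch sizes resolve as `ceil(fraction·n)`.
- The sketch is not padded to exactly `k` centers when the cover is
  smaller (coverage, not count, is the objective); opt-in farthest-point
  padding is available (`pad_to_size`), with deterministic first-index
  tie-breaks.
- All emitted indices are 0-based; MTX files keep that format's 1-based
  convention internally.

## Known limitations

- The thresholding search can return a radius above the true greedy
  feasibility frontier on instances with strongly fragmented feasibility
  (see above); covering validity is never affected.
- Fairness plus hybrid mode can fail when the grid drops a class below
  its quota; the error propagates rather than force-including cells.
- The hybrid inflation bound is asserted for euclidean geometry only.
- Memory is `O(n²)` for the distance matrix in direct mode; the hybrid
  path is the intended route for `n` beyond a few tens of thousands.
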