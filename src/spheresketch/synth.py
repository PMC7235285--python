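"""Seeded synthetic embeddings with abundant and rare populations.

The generator emulates a PCA-like embedding of an scRNA-seq dataset: a
Gaussian mixture in low dimension whose components have very unequal
abundances (rare populations down to ~1%) plus isotropic noise.  That is
the geometry spherical sketching targets — dense dominant clusters that a
uniform subsample over-represents, and small distant clusters it misses.

It makes no attempt to simulate counts (dropout, library size); sketching
operates on an embedding, so the mixture is the right level of realism for
exercising the pipeline.  Labels can be emitted per component or as cycling
collection time points ``t0/t24/t48/t72``, mirroring a 72-hour
differentiation time course sampled every 24 hours.

:func:`generate_outlier_timepoints` additionally plants cells whose
coordinates come from one component but whose time-point label belongs to
another — the "collected at the wrong time" cells fairness-constrained
sketching should avoid selecting as centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cloud import PointCloud

TIME_POINTS = ("t0", "t24", "t48", "t72")


@dataclass
class Component:
    mean: np.ndarray
    stdev: float
    weight: float


@dataclass
class SyntheticConfig:
    """Mixture specification for a synthetic embedding.

    components : (mean, isotropic stdev, abundance weight) triples; weights
        must be positive and are normalised to sum to one.
    rare_index : which component (if any) is flagged as the rare population.
    labels_as : "component" gives component names; "time_point" cycles the
        four 24-hour collection time points over components.
    """

    n_cells: int
    n_dims: int
    components: list
    rare_index: int | None = None
    labels_as: str = "component"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_dims < 1:
            raise ValueError("n_cells and n_dims must be positive")
        if not self.components:
            raise ValueError("need at least one mixture component")
        comps = []
        for spec in self.components:
            mean, stdev, weight = (spec.mean, spec.stdev, spec.weight) if isinstance(spec, Component) else spec
            mean = np.asarray(mean, dtype=np.float64)
            if mean.shape != (self.n_dims,):
                raise ValueError(f"component mean shape {mean.shape} != ({self.n_dims},)")
            if stdev < 0:
                raise ValueError("component stdev must be nonnegative")
            if not weight > 0 or not np.isfinite(weight):
                raise ValueError(f"component weights must be positive, got {weight}")
            comps.append(Component(mean, float(stdev), float(weight)))
        total = sum(c.weight for c in comps)
        for c in comps:
            c.weight /= total
        self.components = comps
        if self.labels_as not in ("component", "time_point"):
            raise ValueError(f"unknown labels_as {self.labels_as!r}")
        if self.rare_index is not None and not 0 <= self.rare_index < len(comps):
            raise ValueError("rare_index out of range")

    def component_label(self, idx: int) -> str:
        if self.labels_as == "time_point":
            return TIME_POINTS[idx % len(TIME_POINTS)]
        return f"component_{idx}"


def default_mixture(
    n_cells: int = 5_000,
    n_dims: int = 10,
    n_components: int = 5,
    rare_weight: float = 0.01,
    stdev: float = 1.0,
    separation: float = 8.0,
    labels_as: str = "component",
    seed: int = 0,
) -> SyntheticConfig:
    """The standard study mixture: well-separated components, one rare.

    Component means are placed at ``separation`` along distinct axes (and
    random directions beyond dimension count), the last component carries
    ``rare_weight`` of the mass, and the rest split the remainder equally.
    """
    rng = np.random.default_rng(seed)
    means = []
    for i in range(n_components):
        if i < n_dims:
            mean = np.zeros(n_dims)
            mean[i] = separation * (1 if i % 2 == 0 else -1)
        else:
            direction = rng.standard_normal(n_dims)
            mean = separation * direction / np.linalg.norm(direction)
        means.append(mean)
    abundant = (1.0 - rare_weight) / (n_components - 1) if n_components > 1 else 1.0
    components = [(means[i], stdev, abundant) for i in range(n_components - 1)]
    components.append((means[-1], stdev, rare_weight if n_components > 1 else 1.0))
    return SyntheticConfig(
        n_cells=n_cells,
        n_dims=n_dims,
        components=components,
        rare_index=n_components - 1 if n_components > 1 else None,
        labels_as=labels_as,
        seed=seed,
    )


def generate_mixture(config: SyntheticConfig):
    """Draw the mixture; returns ``(PointCloud, labels)``.

    Component membership is drawn from the weight vector, coordinates are
    the component mean plus isotropic Gaussian noise.  Fully reproducible
    per seed: the same config gives bitwise-identical output.
    """
    rng = np.random.default_rng(config.seed)
    weights = np.array([c.weight for c in config.components])
    membership = rng.choice(len(weights), size=config.n_cells, p=weights)
    noise = rng.standard_normal((config.n_cells, config.n_dims))
    means = np.stack([c.mean for c in config.components])
    stdevs = np.array([c.stdev for c in config.components])
    coords = means[membership] + stdevs[membership, None] * noise
    labels = [config.component_label(int(m)) for m in membership]
    return PointCloud(coords), labels


def component_counts(config: SyntheticConfig, labels) -> dict:
    """Realised cells per label (the label space the config defines)."""
    counts = {config.component_label(i): 0 for i in range(len(config.components))}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    return counts


def rare_cell_indices(config: SyntheticConfig, labels) -> np.ndarray:
    """Indices of cells carrying the rare component's label."""
    if config.rare_index is None:
        return np.empty(0, dtype=np.intp)
    rare_label = config.component_label(config.rare_index)
    return np.flatnonzero(np.asarray(labels, dtype=object) == rare_label)


def generate_outlier_timepoints(config: SyntheticConfig, n_outliers: int):
    """Mixture plus planted label outliers; returns ``(cloud, labels, outlier_idx)``.

    Outliers are cells drawn from one (dense) component whose time-point
    label is swapped for a different component's label — their coordinates
    disagree with their recorded collection time.  With ``n_outliers = 0``
    the output is identical to :func:`generate_mixture`.
    """
    if n_outliers >= config.n_cells:
        raise ValueError("n_outliers must be smaller than n_cells")
    cloud, labels = generate_mixture(config)
    if n_outliers == 0:
        return cloud, labels, np.empty(0, dtype=np.intp)
    if len(config.components) < 2:
        raise ValueError("planting outliers requires at least two components")
    rng = np.random.default_rng(config.seed + 1_000_003)
    host_label = config.component_label(0)
    foreign_labels = sorted({config.component_label(i) for i in range(len(config.components))} - {host_label})
    host_cells = np.flatnonzero(np.asarray(labels, dtype=object) == host_label)
    if host_cells.size < n_outliers:
        raise ValueError("not enough cells in the host component to plant outliers")
    outliers = np.sort(rng.choice(host_cells, size=n_outliers, replace=False))
    labels = list(labels)
    for j, idx in enumerate(outliers):
        labels[idx] = foreign_labels[j % len(foreign_labels)]
    return cloud, labels, outliers


def write_dense_fixture(cloud: PointCloud, labels, prefix: str) -> None:
    """TSV embedding (cells as rows) + one-label-per-line file."""
    np.savetxt(f"{prefix}.embedding.tsv", cloud.coords, delimiter="\t", fmt="%.10g")
    with open(f"{prefix}.labels.txt", "w") as fh:
        fh.writelines(f"{lab}\n" for lab in labels)


def write_mtx_fixture(cloud: PointCloud, prefix: str) -> None:
    """Matrix Market triplet fixture with barcode/feature companions.

    Coordinates are shifted to be nonnegative and rounded to integer
    pseudo-counts, written genes-by-cells as CellRanger does, to exercise
    the sparse reader end to end.
    """
    from scipy import io as spio
    from scipy import sparse

    counts = np.rint(cloud.coords - cloud.coords.min(axis=0)).astype(np.int64)
    spio.mmwrite(f"{prefix}.mtx", sparse.coo_matrix(counts.T))
    with open(f"{prefix}.barcodes.tsv", "w") as fh:
        fh.writelines(f"{cid}\n" for cid in cloud.cell_ids)
    with open(f"{prefix}.features.tsv", "w") as fh:
        fh.writelines(f"feature_{j}\n" for j in range(cloud.n_dims))
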