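"""Groundtruth functional-connectivity matrix and module partition.

Every simulation in this package perturbs a fixed N x N matrix **W** of
pairwise Pearson correlations between brain regions, together with a
node -> module partition (canonical resting-state networks such as the
default mode network). Empirical matrices of this kind come from a single
subject's resting-state scan; here a latent-time-series generator stands in
for that product. Building W as the correlation matrix of actual synthetic
time series (rather than sampling matrix entries directly) guarantees a
valid, positive-semidefinite correlation matrix by construction, mirroring
how an empirical W is produced.

The generator's signal model: one latent signal per module, one global
signal shared by all nodes, and independent node noise. Node i's series is

    x_i(t) = g_i * global(t) + l_i * z_{m(i)}(t) + sum_c c_ic * z_c(t) + s_i * eps_i(t)

with per-node jitter on the loadings so that within-module correlations are
heterogeneous. A small "hub" subset loads on several additional module
signals, producing the heavy right tail of node strength that whole-brain
FC matrices show (highly connected regions are rare).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "ModulePartition",
    "GroundTruthMatrix",
    "DEFAULT_MODULE_SIZES",
    "generate_partition",
    "generate_groundtruth",
    "load_matrix",
    "load_partition",
    "save_matrix",
    "save_partition",
]

#: Default 13-module split of 264 nodes, sized after the canonical
#: resting-state communities of a 264-region functional parcellation.
DEFAULT_MODULE_SIZES: dict[str, int] = {
    "DMN": 58,
    "Visual": 31,
    "SomMot": 35,
    "FPN": 25,
    "DAN": 11,
    "VAN": 9,
    "Salience": 18,
    "CinguloOperc": 14,
    "Auditory": 13,
    "Subcortical": 13,
    "MemoryRetrieval": 5,
    "Cerebellar": 4,
    "Uncertain": 28,
}


class ConfigurationError(ValueError):
    """Invalid generator or design configuration."""


class ValidationError(ValueError):
    """A matrix or partition violates a structural invariant."""


@dataclass(frozen=True)
class ModulePartition:
    """Assignment of each node to exactly one named module."""

    assignments: np.ndarray  # int module index per node, shape (N,)
    module_names: tuple[str, ...]

    def __post_init__(self):
        a = np.asarray(self.assignments, dtype=np.int64)
        object.__setattr__(self, "assignments", a)
        if len(set(self.module_names)) != len(self.module_names):
            raise ValidationError("module labels must be unique")
        if a.min() < 0 or a.max() >= len(self.module_names):
            raise ValidationError("module index out of range")
        counts = np.bincount(a, minlength=len(self.module_names))
        if (counts == 0).any():
            empty = self.module_names[int(np.argmax(counts == 0))]
            raise ValidationError(f"module {empty!r} has no nodes")

    @property
    def n_nodes(self) -> int:
        return self.assignments.shape[0]

    @property
    def n_modules(self) -> int:
        return len(self.module_names)

    def nodes_of(self, label: str) -> np.ndarray:
        """Indices of the nodes in module ``label``."""
        if label not in self.module_names:
            raise KeyError(f"no module named {label!r}")
        return np.flatnonzero(self.assignments == self.module_names.index(label))

    def labels(self) -> np.ndarray:
        """Per-node module label array (dtype object)."""
        return np.asarray(self.module_names, dtype=object)[self.assignments]


@dataclass(frozen=True)
class GroundTruthMatrix:
    """The fixed correlation matrix W plus its module partition.

    ``strict=False`` skips the substantive invariants (positive mean FC,
    within > between contrast) while keeping the structural ones; it exists
    for degenerate generator configurations (e.g. all loadings zero) used
    to probe the sampling-noise floor.
    """

    values: np.ndarray
    partition: ModulePartition
    strict: bool = True

    def __post_init__(self):
        w = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", w)
        validate_correlation_matrix(w)
        if w.shape[0] != self.partition.n_nodes:
            raise ValidationError(
                f"matrix has {w.shape[0]} nodes but partition has {self.partition.n_nodes}"
            )
        if not self.strict:
            return
        same = self.partition.assignments[:, None] == self.partition.assignments[None, :]
        off = ~np.eye(w.shape[0], dtype=bool)
        mean_within = w[same & off].mean()
        mean_between = w[~same].mean()
        if w[off].mean() <= 0:
            raise ValidationError("mean off-diagonal FC must be positive")
        if mean_within <= mean_between:
            raise ValidationError("mean within-module FC must exceed between-module FC")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def mean_fc(self) -> float:
        off = ~np.eye(self.n_nodes, dtype=bool)
        return float(self.values[off].mean())


def validate_correlation_matrix(w: np.ndarray, *, atol: float = 1e-8) -> None:
    """Raise :class:`ValidationError` on the first structural violation."""
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValidationError(f"matrix must be square, got shape {w.shape}")
    bad = np.argwhere(~np.isfinite(w))
    if bad.size:
        i, j = bad[0]
        raise ValidationError(f"non-finite entry at ({i}, {j})")
    asym = np.abs(w - w.T)
    if asym.max() > atol:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValidationError(f"asymmetry {asym[i, j]:.3g} at ({i}, {j}) exceeds tolerance")
    if not np.allclose(np.diag(w), 1.0, atol=atol):
        i = int(np.argmax(np.abs(np.diag(w) - 1.0)))
        raise ValidationError(f"diagonal entry at ({i}, {i}) is {w[i, i]!r}, expected 1")
    over = np.argwhere(np.abs(w) > 1 + atol)
    if over.size:
        i, j = over[0]
        raise ValidationError(f"|r| > 1 at ({i}, {j}): {w[i, j]!r}")


def generate_partition(
    n_nodes: int = 264,
    module_sizes: dict[str, int] | list[int] | None = None,
    seed: int = 0,
) -> ModulePartition:
    """Assign contiguous blocks of nodes to named modules.

    With ``module_sizes=None`` the default 13-module layout is used (scaled
    to ``n_nodes`` proportionally if ``n_nodes != 264``). A plain list of
    sizes gets generic labels ``M01..`` except that the first four modules
    are named DMN/FPN/DAN/Visual so downstream module-targeted designs work.
    """
    if module_sizes is None:
        base = DEFAULT_MODULE_SIZES
        if n_nodes == 264:
            sizes = dict(base)
        else:
            raw = {k: v * n_nodes / 264 for k, v in base.items()}
            sizes = {k: max(1, int(round(v))) for k, v in raw.items()}
            # fix rounding drift on the largest module
            drift = n_nodes - sum(sizes.values())
            sizes["DMN"] += drift
            if sizes["DMN"] < 1:
                raise ConfigurationError(f"n_nodes={n_nodes} too small for 13 modules")
    elif isinstance(module_sizes, dict):
        sizes = dict(module_sizes)
    else:
        reserved = ["DMN", "FPN", "DAN", "Visual"]
        labels = (reserved + [f"M{i + 1:02d}" for i in range(4, len(module_sizes))])[
            : len(module_sizes)
        ]
        sizes = dict(zip(labels, module_sizes))
    total = sum(sizes.values())
    if total != n_nodes:
        raise ConfigurationError(
            f"module sizes sum to {total}, expected n_nodes={n_nodes}"
        )
    if any(s < 1 for s in sizes.values()):
        raise ConfigurationError("every module must have at least one node")
    names = tuple(sizes)
    assignments = np.repeat(np.arange(len(names)), [sizes[k] for k in names])
    return ModulePartition(assignments=assignments, module_names=names)


def generate_groundtruth(
    partition: ModulePartition,
    n_timepoints: int = 200,
    within_loading: float = 0.75,
    between_loading: float = 0.15,
    hub_fraction: float = 0.08,
    seed: int = 0,
    *,
    global_loading: float = 0.22,
    loading_jitter: float = 0.05,
    noise_sd_range: tuple[float, float] = (0.65, 0.9),
    n_hub_modules: int = 7,
    hub_loading: float = 1.1,
) -> GroundTruthMatrix:
    """Generate a groundtruth correlation matrix from latent time series.

    Parameters
    ----------
    partition:
        Node -> module assignment; one latent signal is created per module.
    n_timepoints:
        Length of the latent series. Finite length leaves realistic sampling
        noise in the correlations (the default, 200, corresponds to a 5-min
        scan at a 1.5-s repetition time).
    within_loading, between_loading:
        Mean loading of a node on its own module signal and on each of two
        randomly chosen other module signals; must satisfy
        ``0 <= between_loading < within_loading < 1``.
    hub_fraction:
        Fraction of nodes promoted to hubs, which additionally load on
        ``n_hub_modules`` foreign module signals with loading
        ``hub_loading``; this produces the right-skewed strength tail.
    global_loading:
        Mean loading on the global signal shared by all nodes; set to 0 to
        switch the global signal off (between-module FC then comes only from
        cross-loadings).
    """
    if not (0 <= between_loading <= within_loading < 1) or (
        0 < within_loading <= between_loading
    ):
        raise ConfigurationError(
            f"need 0 <= between_loading < within_loading < 1, got "
            f"{between_loading} / {within_loading}"
        )
    if n_timepoints < 50:
        raise ConfigurationError("n_timepoints must be >= 50")
    rng = substream(seed, 0xC0)
    n = partition.n_nodes
    m = partition.n_modules
    t = int(n_timepoints)

    z = rng.standard_normal((m, t))  # module signals
    g = rng.standard_normal(t)  # global signal

    g_load = np.clip(rng.normal(global_loading, loading_jitter * (global_loading > 0), n), 0, None)
    w_load = np.clip(rng.normal(within_loading, loading_jitter * (within_loading > 0), n), 0.05, None)
    if within_loading == 0:
        w_load = np.zeros(n)
    noise_sd = rng.uniform(*noise_sd_range, n)

    x = g_load[:, None] * g + w_load[:, None] * z[partition.assignments]
    # weak cross-module coupling: each node leans on two foreign modules
    if between_loading > 0 and m > 1:
        for i in range(n):
            others = [c for c in range(m) if c != partition.assignments[i]]
            picks = rng.choice(others, size=min(2, len(others)), replace=False)
            b = np.clip(rng.normal(between_loading, loading_jitter / 2, picks.size), 0, None)
            x[i] += b @ z[picks]
    # hubs: load on several foreign module signals
    n_hubs = int(round(hub_fraction * n))
    if n_hubs and m > 1:
        hubs = rng.choice(n, size=n_hubs, replace=False)
        for i in hubs:
            others = [c for c in range(m) if c != partition.assignments[i]]
            picks = rng.choice(others, size=min(n_hub_modules, len(others)), replace=False)
            x[i] += hub_loading * z[picks].sum(axis=0)
    x += noise_sd[:, None] * rng.standard_normal((n, t))

    w = np.corrcoef(x)
    np.fill_diagonal(w, 1.0)
    w = (w + w.T) / 2
    has_signal = within_loading > 0 or global_loading > 0 or between_loading > 0
    return GroundTruthMatrix(values=w, partition=partition, strict=has_signal)


# ---------------------------------------------------------------------------
# TSV I/O

def save_matrix(gt_or_values, path) -> None:
    """Write a dense matrix as TSV with node-ID header row/column."""
    w = gt_or_values.values if isinstance(gt_or_values, GroundTruthMatrix) else np.asarray(gt_or_values)
    ids = [f"n{i:03d}" for i in range(w.shape[0])]
    pd.DataFrame(w, index=ids, columns=ids).to_csv(path, sep="\t", float_format="%.10g")


def save_partition(partition: ModulePartition, path) -> None:
    """Write a two-column ``node_id<TAB>module_label`` TSV."""
    ids = [f"n{i:03d}" for i in range(partition.n_nodes)]
    pd.DataFrame({"node_id": ids, "module_label": partition.labels()}).to_csv(
        path, sep="\t", index=False
    )


def load_partition(path) -> ModulePartition:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValidationError("partition file needs node_id and module_label columns")
    labels = df.iloc[:, 1].astype(str).to_numpy()
    names = tuple(dict.fromkeys(labels))  # preserve first-seen order
    idx = {k: i for i, k in enumerate(names)}
    return ModulePartition(
        assignments=np.array([idx[v] for v in labels]), module_names=names
    )


def load_matrix(path, partition_path, *, asym_tol: float = 1e-6) -> GroundTruthMatrix:
    """Load a groundtruth matrix + partition from TSV, validating invariants.

    Mild asymmetry (below ``asym_tol``, e.g. from rounded text output) is
    repaired by averaging with the transpose; anything larger is an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    w = df.to_numpy(dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValidationError(f"matrix must be square, got shape {w.shape}")
    asym = np.abs(w - w.T).max() if w.size else 0.0
    if asym <= asym_tol:
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
    validate_correlation_matrix(w)
    return GroundTruthMatrix(values=w, partition=load_partition(partition_path))
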