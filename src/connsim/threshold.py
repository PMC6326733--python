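"""Edge thresholding: proportional, absolute (FC-value) and weighted.

Proportional thresholding (PT) retains the top fraction of edges so that
every subject has exactly the same edge count, density and mean degree
(D = 2E/N(N-1), <k> = 2E/N, hence <k> = D(N-1)). Absolute thresholding
retains edges whose value exceeds a fixed correlation cutoff, so density is
free to differ between subjects. Weighted "thresholding" keeps the
continuous matrix after applying the negative-edge policy.

Negative-edge policy is applied *before* ranking or cutoff comparison:
``discard`` removes negative edges from candidacy (the default, matching
the most common explicit practice in the clinical literature), ``abs``
rectifies them, and ``retain`` passes them through. Ranking for PT uses the
signed post-policy value; ties are broken by stable lexicographic node-pair
order, which also makes PT edge sets nest across densities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ThresholdSpec",
    "ThresholdedGraph",
    "DegenerateGraphError",
    "binarize_proportional",
    "binarize_absolute",
    "to_weighted",
    "density_mean_degree",
    "apply_negative_policy",
    "pt_degrees_batch",
    "absolute_degrees_batch",
    "strengths_batch",
    "pt_edge_order",
]

NEGATIVE_POLICIES = ("discard", "abs", "retain")


class DegenerateGraphError(ValueError):
    """Thresholding produced an empty (or impossible) graph."""


@dataclass(frozen=True)
class ThresholdSpec:
    strategy: str                 # proportional | absolute | weighted
    cutoff: float | None = None   # density (proportional) or r value (absolute)
    negative_policy: str = "discard"

    def __post_init__(self):
        if self.strategy not in ("proportional", "absolute", "weighted"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.negative_policy not in NEGATIVE_POLICIES:
            raise ValueError(f"unknown negative policy {self.negative_policy!r}")
        if self.strategy == "proportional" and not (0 < (self.cutoff or 0) <= 1):
            raise ValueError("proportional cutoff must be a density in (0, 1]")
        if self.strategy == "absolute" and not (abs(self.cutoff or 0) < 1):
            raise ValueError("absolute cutoff must be a correlation in (-1, 1)")


@dataclass(frozen=True)
class ThresholdedGraph:
    adjacency: np.ndarray
    spec: ThresholdSpec
    n_edges: int
    density: float
    mean_degree: float

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def is_binary(self) -> bool:
        a = self.adjacency
        return bool(np.isin(a, (0.0, 1.0)).all())


def apply_negative_policy(values: np.ndarray, policy: str) -> np.ndarray:
    """Apply a negative-edge policy to raw edge values."""
    if policy == "discard":
        return np.where(values > 0, values, 0.0)
    if policy == "abs":
        return np.abs(values)
    if policy == "retain":
        return np.asarray(values, dtype=float)
    raise ValueError(f"unknown negative policy {policy!r}")


def _edge_vector(matrix) -> tuple[np.ndarray, int]:
    m = matrix.values if hasattr(matrix, "values") and not isinstance(matrix, np.ndarray) else np.asarray(matrix)
    n = m.shape[0]
    return m[np.triu_indices(n, k=1)], n


def _graph_from_edges(present: np.ndarray, n: int, spec: ThresholdSpec, weights=None) -> ThresholdedGraph:
    iu, ju = np.triu_indices(n, k=1)
    adj = np.zeros((n, n))
    vals = present.astype(float) if weights is None else np.where(present, weights, 0.0)
    adj[iu, ju] = vals
    adj[ju, iu] = vals
    e = int(np.count_nonzero(present))
    d = 2 * e / (n * (n - 1))
    return ThresholdedGraph(adjacency=adj, spec=spec, n_edges=e, density=d, mean_degree=2 * e / n)


def binarize_proportional(matrix, density: float, negative_policy: str = "discard") -> ThresholdedGraph:
    """Binarize by retaining the top ``round(density * N(N-1)/2)`` edges.

    The edge count is exact for every subject. Negative-policy first, then a
    stable descending sort of the signed post-policy values; ties at the
    cutoff are broken by lexicographic node-pair order.
    """
    spec = ThresholdSpec("proportional", density, negative_policy)
    vals, n = _edge_vector(matrix)
    pv = apply_negative_policy(vals, negative_policy)
    eligible = pv > 0 if negative_policy == "discard" else np.ones(pv.size, dtype=bool)
    m_pairs = pv.size
    e_target = int(np.round(density * m_pairs))  # round-half-even
    if e_target == 0:
        raise DegenerateGraphError(f"density {density} yields 0 edges for N={n}")
    if e_target > int(eligible.sum()):
        raise DegenerateGraphError(
            f"density {density} requires {e_target} edges but only "
            f"{int(eligible.sum())} survive the {negative_policy!r} policy"
        )
    order = np.argsort(-pv, kind="stable")
    present = np.zeros(m_pairs, dtype=bool)
    present[order[:e_target]] = True
    return _graph_from_edges(present, n, spec)


def binarize_absolute(matrix, r_cutoff: float, negative_policy: str = "discard") -> ThresholdedGraph:
    """Binarize by retaining edges whose post-policy value exceeds ``r_cutoff``."""
    spec = ThresholdSpec("absolute", r_cutoff, negative_policy)
    vals, n = _edge_vector(matrix)
    pv = apply_negative_policy(vals, negative_policy)
    present = pv > r_cutoff
    if not present.any():
        raise DegenerateGraphError(
            f"no edges exceed r={r_cutoff} (max observed value {pv.max():.4f})"
        )
    return _graph_from_edges(present, n, spec)


def to_weighted(matrix, negative_policy: str = "discard") -> ThresholdedGraph:
    """Weighted graph after the stated negative-edge policy."""
    spec = ThresholdSpec("weighted", None, negative_policy)
    vals, n = _edge_vector(matrix)
    pv = apply_negative_policy(vals, negative_policy)
    present = pv != 0
    return _graph_from_edges(present, n, spec, weights=pv)


def density_mean_degree(graph: ThresholdedGraph) -> tuple[int, float, float]:
    """(E, D, <k>) of a binary graph; the identity <k> = D(N-1) is exact."""
    if not graph.is_binary:
        raise TypeError("density/mean-degree bookkeeping is defined for binary graphs")
    n = graph.n_nodes
    e = int(graph.adjacency.sum() // 2)
    d = 2 * e / (n * (n - 1))
    return e, d, 2 * e / n


# ---------------------------------------------------------------------------
# batch paths over condensed cohort arrays (one row per subject)


def pt_edge_order(edge_values: np.ndarray, negative_policy: str = "discard"):
    """Stable descending edge ranking per subject; returns (order, n_eligible)."""
    pv = apply_negative_policy(edge_values, negative_policy)
    order = np.argsort(-pv, axis=-1, kind="stable")
    if negative_policy == "discard":
        n_eligible = (pv > 0).sum(axis=-1)
    else:
        n_eligible = np.full(pv.shape[:-1], pv.shape[-1], dtype=np.int64)
    return order, n_eligible


def pt_degrees_batch(
    edge_values: np.ndarray,
    n_nodes: int,
    densities,
    negative_policy: str = "discard",
) -> np.ndarray:
    """Degrees under PT for every subject and density.

    ``edge_values``: (S, M) condensed subject edges. Returns (S, D, N).
    """
    iu, ju = np.triu_indices(n_nodes, k=1)
    densities = np.asarray(densities, dtype=float)
    m_pairs = edge_values.shape[1]
    targets = np.round(densities * m_pairs).astype(int)
    order, n_eligible = pt_edge_order(edge_values, negative_policy)
    out = np.zeros((edge_values.shape[0], densities.size, n_nodes), dtype=np.int64)
    for s in range(edge_values.shape[0]):
        if targets.max() > n_eligible[s]:
            raise DegenerateGraphError(
                f"subject {s}: density {densities[targets.argmax()]} needs "
                f"{targets.max()} edges, only {int(n_eligible[s])} eligible"
            )
        for k, e_t in enumerate(targets):
            top = order[s, :e_t]
            out[s, k] = np.bincount(iu[top], minlength=n_nodes) + np.bincount(
                ju[top], minlength=n_nodes
            )
    return out


def absolute_degrees_batch(
    edge_values: np.ndarray,
    n_nodes: int,
    cutoffs,
    negative_policy: str = "discard",
):
    """Degrees and per-subject densities under absolute thresholding.

    Returns ``(degrees (S, C, N), densities (S, C))``.
    """
    iu, ju = np.triu_indices(n_nodes, k=1)
    cutoffs = np.asarray(cutoffs, dtype=float)
    pv = apply_negative_policy(edge_values, negative_policy)
    m_pairs = pv.shape[1]
    degs = np.zeros((pv.shape[0], cutoffs.size, n_nodes), dtype=np.int64)
    dens = np.zeros((pv.shape[0], cutoffs.size))
    for s in range(pv.shape[0]):
        order = np.argsort(-pv[s], kind="stable")
        sorted_desc = pv[s, order]
        for k, c in enumerate(cutoffs):
            e_c = int(np.searchsorted(-sorted_desc, -c, side="left"))  # values > c
            top = order[:e_c]
            degs[s, k] = np.bincount(iu[top], minlength=n_nodes) + np.bincount(
                ju[top], minlength=n_nodes
            )
            dens[s, k] = e_c / m_pairs
    return degs, dens


def strengths_batch(
    edge_values: np.ndarray, n_nodes: int, negative_policy: str = "discard"
) -> np.ndarray:
    """Nodal strength (sum of policy-applied incident weights); (S, N)."""
    iu, ju = np.triu_indices(n_nodes, k=1)
    pv = apply_negative_policy(edge_values, negative_policy)
    out = np.zeros((pv.shape[0], n_nodes))
    np.add.at(out.T, iu, pv.T)
    np.add.at(out.T, ju, pv.T)
    return out
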