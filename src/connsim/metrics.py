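"""Graph statistics: degree, strength, modular degree, transitivity,
characteristic path length, degree-preserving rewiring and small-worldness.

Small-worldness follows the classical clustering-vs-path-length ratio

    sigma = (C_g / C_rand) / (L_g / L_rand)

where ``C`` is the global transitivity (3 x triangles / connected triples,
not mean local clustering), ``L`` the mean shortest-path length over
reachable pairs, and the ``rand`` terms are averages over an ensemble of
degree-preserving rewired null graphs (Maslov–Sneppen double edge swaps).
Values much larger than 1 indicate small-world topology; a random graph is
its own null and sits near 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from ._graphfast import (
    bfs_path_stats,
    edges_to_csr,
    rewire_edges,
    transitivity_from_edges,
)
from .groundtruth import ModulePartition
from .threshold import ThresholdedGraph

__all__ = [
    "degree",
    "strength",
    "module_degree",
    "zscore_by_module_density",
    "transitivity",
    "char_path_length",
    "PathLengthResult",
    "rewire_preserving_degree",
    "small_worldness",
    "SmallWorldResult",
    "attempted_swap_budget",
    "UndefinedSigmaError",
]


class UndefinedSigmaError(ArithmeticError):
    """sigma is undefined (e.g. the null ensemble has zero transitivity)."""


def _adjacency(graph) -> np.ndarray:
    if isinstance(graph, ThresholdedGraph):
        return graph.adjacency
    return np.asarray(graph, dtype=float)


def _require_binary(adj: np.ndarray, what: str) -> None:
    if not np.isin(adj, (0.0, 1.0)).all():
        raise TypeError(f"{what} is defined for binary graphs; got weighted input")


def _edge_array(adj: np.ndarray) -> np.ndarray:
    iu, ju = np.nonzero(np.triu(adj, k=1))
    return np.column_stack([iu, ju]).astype(np.int64)


def degree(graph) -> np.ndarray:
    """Per-node count of incident edges (binary graphs)."""
    adj = _adjacency(graph)
    _require_binary(adj, "degree")
    return adj.sum(axis=1).astype(np.int64)


def strength(graph) -> np.ndarray:
    """Per-node sum of incident weights; reduces to degree on binary input."""
    adj = _adjacency(graph)
    return adj.sum(axis=1)


def module_degree(graph, partition: ModulePartition, scope: str) -> np.ndarray:
    """Incident edges to same-module (``within``) or other-module
    (``between``) neighbors; within + between equals degree."""
    if scope not in ("within", "between"):
        raise ValueError(f"scope must be 'within' or 'between', got {scope!r}")
    adj = _adjacency(graph)
    _require_binary(adj, "module degree")
    if adj.shape[0] != partition.n_nodes:
        raise ValueError(
            f"graph has {adj.shape[0]} nodes but partition covers {partition.n_nodes}"
        )
    same = partition.assignments[:, None] == partition.assignments[None, :]
    mask = same if scope == "within" else ~same
    return (adj * mask).sum(axis=1).astype(np.int64)


def zscore_by_module_density(
    table: pd.DataFrame,
    value_col: str = "value",
    by: tuple[str, ...] = ("module", "density"),
) -> pd.DataFrame:
    """z-score values within each (module, density) stratum (ddof=1).

    Returns a copy with a ``z`` column and a boolean ``zero_variance`` flag;
    zero-variance strata produce NaN z values and are flagged, not dropped.
    """
    out = table.copy()
    grouped = out.groupby(list(by), observed=True)[value_col]
    counts = grouped.transform("count")
    if (counts < 2).any():
        raise ValueError("every (module, density) stratum needs at least 2 values")
    mean = grouped.transform("mean")
    sd = grouped.transform("std")  # pandas std is ddof=1
    with np.errstate(invalid="ignore", divide="ignore"):
        out["z"] = (out[value_col] - mean) / sd
    out["zero_variance"] = (sd == 0).to_numpy()
    if out["zero_variance"].any():
        n = int(out.loc[out.zero_variance].groupby(list(by), observed=True).ngroups)
        warnings.warn(f"{n} zero-variance strata produced NaN z-scores", stacklevel=2)
    return out


def transitivity(graph) -> float:
    """Global transitivity: 3 x triangles / connected triples."""
    adj = _adjacency(graph)
    _require_binary(adj, "transitivity")
    c, triples = transitivity_from_edges(_edge_array(adj), adj.shape[0])
    if triples == 0:
        warnings.warn("graph has no connected triples; transitivity defined as 0", stacklevel=2)
    return float(c)


class PathLengthResult(NamedTuple):
    length: float
    n_unreachable_pairs: int  # ordered pairs excluded from the mean

    def __float__(self):
        return self.length


def char_path_length(graph) -> PathLengthResult:
    """Mean shortest-path length over reachable ordered pairs.

    Disconnected pairs are excluded from the mean and their (ordered) count
    reported alongside.
    """
    adj = _adjacency(graph)
    _require_binary(adj, "path length")
    edges = _edge_array(adj)
    n = adj.shape[0]
    indptr, indices = edges_to_csr(edges, n)
    total, reached, unreached = bfs_path_stats(indptr, indices, n)
    if reached == 0:
        raise UndefinedSigmaError("graph has no connected pairs; path length undefined")
    return PathLengthResult(total / reached, int(unreached))


def attempted_swap_budget(
    n_nodes: int, n_edges: int, swaps_per_edge: int = 10, budget: str = "edges"
) -> int:
    """Number of attempted swaps for the rewiring null.

    ``budget='edges'`` scales with the actual edge count (10 x E by
    default); ``budget='pairs'`` scales with the number of unique node
    pairs, 10 x N(N-1)/2 — for a 264-node graph, 347,160 attempts.
    """
    if budget == "edges":
        return int(swaps_per_edge * n_edges)
    if budget == "pairs":
        return int(swaps_per_edge * n_nodes * (n_nodes - 1) // 2)
    raise ValueError(f"unknown budget {budget!r}")


def rewire_preserving_degree(
    graph,
    swaps_per_edge: int = 10,
    rng: np.random.Generator | int | None = None,
    budget: str = "edges",
):
    """Degree-preserving randomization by double edge swaps.

    Executes ``attempted_swap_budget`` attempted swaps, rejecting any that
    would create self-loops or multi-edges; the degree sequence is exactly
    preserved. Returns a graph of the same type as the input.
    """
    adj = _adjacency(graph)
    _require_binary(adj, "rewiring")
    edges = _edge_array(adj)
    if edges.shape[0] < 2:
        raise ValueError("rewiring needs at least 2 edges")
    n = adj.shape[0]
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    seed = int(rng.integers(0, 2**31 - 1))
    rewire_edges(edges, n, attempted_swap_budget(n, edges.shape[0], swaps_per_edge, budget), seed)
    out = np.zeros_like(adj)
    out[edges[:, 0], edges[:, 1]] = 1.0
    out[edges[:, 1], edges[:, 0]] = 1.0
    if isinstance(graph, ThresholdedGraph):
        return ThresholdedGraph(
            adjacency=out,
            spec=graph.spec,
            n_edges=graph.n_edges,
            density=graph.density,
            mean_degree=graph.mean_degree,
        )
    return out


@dataclass(frozen=True)
class SmallWorldResult:
    sigma: float
    C_g: float
    L_g: float
    C_rand: float
    L_rand: float
    n_null: int
    component_coverage: float = 1.0  # fraction of nodes in the component analyzed


def _largest_component_edges(edges: np.ndarray, n: int):
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    a = coo_matrix(
        (np.ones(edges.shape[0] * 2), (np.r_[edges[:, 0], edges[:, 1]], np.r_[edges[:, 1], edges[:, 0]])),
        shape=(n, n),
    )
    n_comp, labels = connected_components(a, directed=False)
    if n_comp == 1:
        return edges, n, 1.0
    keep_label = np.bincount(labels).argmax()
    keep = np.flatnonzero(labels == keep_label)
    remap = np.full(n, -1, dtype=np.int64)
    remap[keep] = np.arange(keep.size)
    mask = (labels[edges[:, 0]] == keep_label) & (labels[edges[:, 1]] == keep_label)
    sub = remap[edges[mask]]
    return sub, keep.size, keep.size / n


def small_worldness(
    graph,
    n_null: int = 100,
    swaps_per_edge: int = 10,
    rng: np.random.Generator | int | None = None,
    budget: str = "edges",
) -> SmallWorldResult:
    """sigma of a graph against a degree-preserving rewired null ensemble.

    Disconnected graphs are reduced to their largest connected component
    (coverage reported in the result); each null graph is an independent
    rewiring of the target.
    """
    adj = _adjacency(graph)
    _require_binary(adj, "small-worldness")
    edges = _edge_array(adj)
    if edges.shape[0] < 2:
        raise ValueError("small-worldness needs at least 2 edges")
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    edges, n, coverage = _largest_component_edges(edges, adj.shape[0])
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    c_g, _ = transitivity_from_edges(edges, n)
    indptr, indices = edges_to_csr(edges, n)
    total, reached, _ = bfs_path_stats(indptr, indices, n)
    l_g = total / reached
    n_attempts = attempted_swap_budget(n, edges.shape[0], swaps_per_edge, budget)

    c_sum = 0.0
    l_sum = 0.0
    for _ in range(n_null):
        e = edges.copy()
        rewire_edges(e, n, n_attempts, int(rng.integers(0, 2**31 - 1)))
        c_k, _ = transitivity_from_edges(e, n)
        c_sum += c_k
        indptr, indices = edges_to_csr(e, n)
        total, reached, _ = bfs_path_stats(indptr, indices, n)
        l_sum += total / reached
    c_rand = c_sum / n_null
    l_rand = l_sum / n_null
    if c_rand == 0:
        raise UndefinedSigmaError(
            f"null ensemble transitivity is 0 (C_g={c_g:.4f}, L_g={l_g:.4f}, "
            f"L_rand={l_rand:.4f}); sigma undefined"
        )
    return SmallWorldResult(
        sigma=float((c_g / c_rand) / (l_g / l_rand)),
        C_g=float(c_g),
        L_g=float(l_g),
        C_rand=float(c_rand),
        L_rand=float(l_rand),
        n_null=n_null,
        component_coverage=float(coverage),
    )
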