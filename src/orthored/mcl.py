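"""Markov clustering of the reduced dataset from the pairwise e-value matrix.

The similarity graph carries ``max(0, -log10 e)`` edge weights, symmetrized
by taking the better of the two search directions, with a self-loop on each
node equal to its maximum incident weight (standard MCL regularization).
Clustering runs the classic expansion/inflation iteration on the dense
column-stochastic matrix; the default inflation of 1.2 is deliberately lax
so that true orthologs are rarely split before tree building.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .simsearch import SimilarityMatrix

__all__ = [
    "SimilarityGraph",
    "Clustering",
    "graph_from_matrix",
    "mcl_cluster",
    "cluster_of_interest",
]

DEFAULT_INFLATION = 1.2


@dataclass
class SimilarityGraph:
    """Symmetric non-negative weight matrix over ordered sequence IDs."""

    ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.ids), len(self.ids)):
            raise ValueError("weight matrix shape does not match ids")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        self.weights = w


@dataclass
class Clustering:
    """A partition of the node set into disjoint non-empty clusters."""

    clusters: list[frozenset[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            if not c:
                raise ValueError("empty cluster")
            if seen & c:
                raise ValueError("clusters overlap")
            seen |= c

    @property
    def nodes(self) -> set[str]:
        return set().union(*self.clusters) if self.clusters else set()


def graph_from_matrix(m: SimilarityMatrix) -> SimilarityGraph:
    """Turn the directional e-value matrix into a symmetric weighted graph.

    ``w(i, j) = max(0, max(-log10 e_ij, -log10 e_ji))`` for i != j; the
    self-loop of each node is its maximum incident weight (1.0 when the
    node has no positive-weight neighbor).
    """
    logs = -np.log10(m.evalues)
    w = np.maximum(logs, logs.T)
    np.fill_diagonal(w, 0.0)
    w = np.maximum(w, 0.0)
    incident = w.max(axis=1)
    loops = np.where(incident > 0, incident, 1.0)
    np.fill_diagonal(w, loops)
    return SimilarityGraph(list(m.ids), w)


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=0)
    sums[sums == 0] = 1.0
    return m / sums


def mcl_cluster(
    g: SimilarityGraph,
    inflation: float = DEFAULT_INFLATION,
    expansion: int = 2,
    max_iter: int = 200,
    tol: float = 1e-6,
    prune: float = 1e-8,
    iterate_hook=None,
) -> Clustering:
    """Markov clustering of a similarity graph.

    Iterates matrix power (`expansion`), entrywise power (`inflation`) with
    column re-normalization, and pruning of entries below `prune`, until the
    largest entry change drops below `tol` or `max_iter` is reached.
    Clusters are read off the limit matrix as attractor systems plus the
    nodes they attract; a node attracted to several systems goes to the one
    with the larger total attraction, ties to the system containing the
    alphanumerically smallest attractor.

    `iterate_hook`, when given, is called with the column-stochastic matrix
    after every iteration (useful for instrumentation).
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    m = _normalize_columns(g.weights.copy())
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = _normalize_columns(np.power(m, inflation))
        m[m < prune] = 0.0
        m = _normalize_columns(m)
        if iterate_hook is not None:
            iterate_hook(m)
        if np.max(np.abs(m - prev)) < tol:
            break
    return _interpret_limit(m, g.ids, prune)


def _interpret_limit(m: np.ndarray, ids: Sequence[str], prune: float) -> Clustering:
    """Read clusters from an (approximate) MCL limit matrix."""
    n = len(ids)
    attractors = [i for i in range(n) if m[i, i] > prune]
    if not attractors:  # pathological; should not happen on a converged run
        attractors = list(range(n))
    # attractor systems: attractors connected through each other's rows
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        parent[find(a)] = find(b)

    attractor_set = set(attractors)
    for i in attractors:
        for j in attractors:
            if i != j and (m[i, j] > prune or m[j, i] > prune):
                union(i, j)
    systems: dict[int, list[int]] = {}
    for i in attractors:
        systems.setdefault(find(i), []).append(i)
    system_list = list(systems.values())
    # representative = alphanumerically smallest attractor id, for tie-breaks
    reps = [min(ids[i] for i in sys) for sys in system_list]

    assignment: dict[int, int] = {}
    for k, sys in enumerate(system_list):
        for i in sys:
            assignment[i] = k
    for j in range(n):
        if j in attractor_set:
            continue
        attraction = [sum(m[i, j] for i in sys) for sys in system_list]
        best = max(attraction)
        if best <= 0:
            # no attractor pulls this node; make it a singleton system
            system_list.append([j])
            reps.append(ids[j])
            assignment[j] = len(system_list) - 1
            continue
        candidates = [k for k, a in enumerate(attraction) if a == best]
        assignment[j] = min(candidates, key=lambda k: reps[k])
    clusters: dict[int, set[str]] = {}
    for j, k in assignment.items():
        clusters.setdefault(k, set()).add(ids[j])
    ordered = sorted(clusters.values(), key=lambda c: min(c))
    return Clustering([frozenset(c) for c in ordered])


def cluster_of_interest(c: Clustering, query_id: str) -> frozenset[str]:
    """The unique cluster containing the query."""
    for cluster in c.clusters:
        if query_id in cluster:
            return cluster
    raise KeyError(f"query {query_id!r} not found in any cluster")
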