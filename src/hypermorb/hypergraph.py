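"""Weighted hypergraph construction and eigenvector centrality.

Diseases are nodes; every multimorbidity cluster — a set of >= 2 diseases
observed together in at least one participant — is a hyperedge. The
incidence matrix ``M`` (edges x diseases) represents the unweighted
hypergraph. Each edge carries an overlap weight

    W_E(e) = #{participants with every disease in e}
             / min over d in e of #{participants with d},

a measure of how nested the cluster is (1 means the rarest member never
occurs outside the cluster). Each disease carries its crude prevalence
W_N(d) = count(d) / n.

Node-level adjacency:  A  = M^T W_E M  with the diagonal zeroed
(a node is not adjacent to itself). Dual (cluster-level) adjacency:
A* = W_E (M W_N M^T - D_E) W_E, i.e. two clusters are adjacent in
proportion to the summed prevalence of their shared diseases, scaled by
both overlap weights, again with a zero diagonal.

Eigenvector centrality is the leading eigenvector of the adjacency
matrix, sign-fixed to non-negative entries (Perron-Frobenius) and scaled
to unit Euclidean norm.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components

from .catalog import DiseaseCatalog
from .errors import DegenerateGraphError, UndefinedWeightError

EdgeUniverse = Literal["profiles", "subsets"]
Counting = Literal["superset", "exact"]

EDGE_LABEL_SEPARATOR = "|"


@dataclass(frozen=True)
class Hyperedge:
    """A multimorbidity cluster: >= 2 diseases with its support and weight."""

    diseases: tuple[str, ...]       # in catalog order
    indices: tuple[int, ...]        # catalog positions, ascending
    member_count: int               # participants having all member diseases
    weight: float                   # overlap weighting coefficient W_E, in (0, 1]

    @property
    def label(self) -> str:
        return EDGE_LABEL_SEPARATOR.join(self.diseases)


@dataclass(frozen=True)
class IncidenceStructure:
    """Incidence matrix plus the node and edge weights of a weighted hypergraph."""

    M: np.ndarray                   # edges x diseases, 0/1
    edges: tuple[Hyperedge, ...]
    W_E: np.ndarray                 # per-edge overlap weights
    W_N: np.ndarray                 # per-disease crude prevalence
    n_participants: int
    catalog: DiseaseCatalog

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Symmetric non-negative matrix with zero diagonal, node- or dual-level."""

    values: np.ndarray
    labels: tuple[str, ...]
    level: Literal["node", "dual"]


@dataclass(frozen=True)
class CentralityTable:
    """Eigenvector centralities (unit Euclidean norm) with the leading eigenvalue."""

    labels: tuple[str, ...]
    centrality: np.ndarray
    eigenvalue: float

    def as_dict(self) -> dict[str, float]:
        return {lab: float(c) for lab, c in zip(self.labels, self.centrality)}


def overlap_weight(indices: Sequence[int], matrix: np.ndarray) -> float:
    """Overlap weighting coefficient for a disease set over a 0/1 cohort matrix."""
    idx = list(indices)
    cols = matrix[:, idx]
    singles = cols.sum(axis=0)
    if (singles == 0).any():
        zero = [idx[i] for i in np.flatnonzero(singles == 0)]
        raise UndefinedWeightError(f"disease column(s) {zero} have zero cases")
    all_count = int(cols.all(axis=1).sum())
    return all_count / int(singles.min())


def enumerate_hyperedges(matrix: np.ndarray, catalog: DiseaseCatalog,
                         edge_universe: EdgeUniverse = "profiles",
                         counting: Counting = "superset",
                         min_support: int = 1) -> list[Hyperedge]:
    """Enumerate multimorbidity clusters from a participant x disease 0/1 matrix.

    In the default ``profiles`` universe each edge is a distinct complete
    diagnosis profile of size >= 2 observed in at least one participant; the
    ``subsets`` universe additionally includes every size >= 2 subset of an
    observed profile. ``member_count`` uses superset semantics by default
    (participants with all member diseases, possibly more); ``exact``
    counts only participants whose full profile equals the edge. Edges with
    ``member_count < min_support`` are dropped. Output order is canonical:
    by edge size, then lexicographically by catalog indices.
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != len(catalog):
        raise ValueError("matrix must be participants x catalog diseases")
    profiles, counts = np.unique(matrix, axis=0, return_counts=True)
    exact_count = {tuple(np.flatnonzero(p)): int(c) for p, c in zip(profiles, counts)}

    candidate_sets: set[tuple[int, ...]] = set()
    for p in profiles:
        idx = tuple(int(i) for i in np.flatnonzero(p))
        if len(idx) < 2:
            continue
        if edge_universe == "profiles":
            candidate_sets.add(idx)
        elif edge_universe == "subsets":
            candidate_sets.update(_subsets_of(idx))
        else:
            raise ValueError(f"unknown edge universe {edge_universe!r}")

    edges: list[Hyperedge] = []
    for idx in sorted(candidate_sets, key=lambda s: (len(s), s)):
        if counting == "superset":
            member_count = int(matrix[:, list(idx)].all(axis=1).sum())
        elif counting == "exact":
            member_count = exact_count.get(idx, 0)
        else:
            raise ValueError(f"unknown counting mode {counting!r}")
        if member_count < max(min_support, 1):
            continue
        edges.append(Hyperedge(
            diseases=tuple(catalog.names[i] for i in idx),
            indices=idx,
            member_count=member_count,
            weight=overlap_weight(idx, matrix),
        ))
    return edges


def _subsets_of(indices: tuple[int, ...]):
    from itertools import combinations
    for size in range(2, len(indices) + 1):
        yield from combinations(indices, size)


def build_incidence(matrix: np.ndarray, catalog: DiseaseCatalog,
                    edge_universe: EdgeUniverse = "profiles",
                    counting: Counting = "superset",
                    min_support: int = 1) -> IncidenceStructure:
    """Assemble the full weighted-hypergraph structure for a cohort matrix."""
    matrix = np.asarray(matrix)
    edges = enumerate_hyperedges(matrix, catalog, edge_universe, counting, min_support)
    M = np.zeros((len(edges), len(catalog)), dtype=np.int8)
    for row, e in enumerate(edges):
        M[row, list(e.indices)] = 1
    W_E = np.array([e.weight for e in edges], dtype=float)
    W_N = matrix.sum(axis=0).astype(float) / matrix.shape[0]
    return IncidenceStructure(M=M, edges=tuple(edges), W_E=W_E, W_N=W_N,
                              n_participants=int(matrix.shape[0]), catalog=catalog)


def node_adjacency(inc: IncidenceStructure) -> AdjacencyMatrix:
    """Disease x disease adjacency A = M^T W_E M with zero diagonal."""
    A = inc.M.T.astype(float) @ np.diag(inc.W_E) @ inc.M.astype(float)
    np.fill_diagonal(A, 0.0)
    return AdjacencyMatrix(values=A, labels=tuple(inc.catalog.names), level="node")


def dual_adjacency(inc: IncidenceStructure) -> AdjacencyMatrix:
    """Edge x edge dual adjacency A* = W_E (M W_N M^T - D_E) W_E."""
    inner = inc.M.astype(float) @ np.diag(inc.W_N) @ inc.M.T.astype(float)
    A = np.diag(inc.W_E) @ inner @ np.diag(inc.W_E)
    np.fill_diagonal(A, 0.0)
    return AdjacencyMatrix(values=A, labels=tuple(e.label for e in inc.edges), level="dual")


def power_iteration(values: np.ndarray, tol: float = 1e-12,
                    max_iter: int = 10_000) -> tuple[np.ndarray, float]:
    """Leading eigenpair of a symmetric non-negative matrix by power iteration."""
    n = values.shape[0]
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        y = values @ x
        norm = np.linalg.norm(y)
        if norm == 0.0:
            raise DegenerateGraphError("power iteration hit the zero vector")
        y /= norm
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    eigenvalue = float(x @ values @ x)
    return x, eigenvalue


def eigenvector_centrality(adj: AdjacencyMatrix,
                           method: Literal["dense", "power"] = "dense") -> CentralityTable:
    """Leading-eigenvector centrality of an adjacency matrix.

    The returned vector is non-negative with unit Euclidean norm. On a
    disconnected graph the centrality is the leading eigenvector of the
    connected component attaining the largest eigenvalue; entries outside
    that component are zero. Raises :class:`DegenerateGraphError` on an
    all-zero matrix.
    """
    A = np.asarray(adj.values, dtype=float)
    if A.size == 0 or not (A > 0).any():
        raise DegenerateGraphError("adjacency matrix has no positive entry")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency matrix must be symmetric")

    if method == "power":
        vec, eigenvalue = power_iteration(A)
    elif method == "dense":
        n_comp, comp = connected_components(A != 0, directed=False)
        best: tuple[float, np.ndarray] | None = None
        for c in range(n_comp):
            nodes = np.flatnonzero(comp == c)
            if len(nodes) == 1:
                continue
            sub = A[np.ix_(nodes, nodes)]
            w, v = scipy.linalg.eigh(sub)
            lam = float(w[-1])
            if best is None or lam > best[0] + 0.0:
                full = np.zeros(A.shape[0])
                full[nodes] = v[:, -1]
                best = (lam, full)
        if best is None:
            raise DegenerateGraphError("no connected component with >= 2 nodes")
        eigenvalue, vec = best
    else:
        raise ValueError(f"unknown method {method!r}")

    if vec.sum() < 0:
        vec = -vec
    if vec.min() < -1e-8:
        raise DegenerateGraphError(
            "leading eigenvector has mixed signs beyond tolerance; "
            "the dominant eigenvalue may be degenerate")
    vec = np.clip(vec, 0.0, None)
    vec = vec / np.linalg.norm(vec)
    return CentralityTable(labels=adj.labels, centrality=vec, eigenvalue=eigenvalue)


def rank_centralities(table: CentralityTable) -> list[tuple[str, float, int]]:
    """Order centralities descending; ties share the lower rank number.

    Tied labels keep their input (catalog) order. Returns
    ``(label, centrality, rank)`` triples with unrounded centralities;
    round to 2 decimals for display.
    """
    order = sorted(range(len(table.labels)),
                   key=lambda i: (-table.centrality[i], i))
    out: list[tuple[str, float, int]] = []
    prev_value: float | None = None
    prev_rank = 0
    for pos, i in enumerate(order, start=1):
        value = float(table.centrality[i])
        rank = prev_rank if value == prev_value else pos
        out.append((table.labels[i], value, rank))
        prev_value, prev_rank = value, rank
    return out
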