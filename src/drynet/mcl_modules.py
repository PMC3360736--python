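"""Markov Cluster (MCL) module detection on weighted co-expression networks.

MCL simulates random walks on the graph by alternating *expansion* (matrix
power of a column-stochastic transition matrix) and *inflation* (entrywise
power followed by column renormalization). Expansion spreads flow along
paths; inflation strengthens strong flows and starves weak ones. The process
converges to a sparse idempotent-like limit whose attractor structure defines
the clustering. Lower inflation yields coarser modules; the default of 1.2
gives the large functional modules typical of co-expression networks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

logger = logging.getLogger(__name__)

UNASSIGNED = 0  # sentinel module id for genes outside every module


@dataclass(frozen=True)
class MCLParams:
    """Parameters of the Markov Cluster iteration.

    inflation
        Entrywise power applied after expansion; must exceed 1. Larger values
        produce finer clusters.
    expansion
        Power of the stochastic matrix per iteration (2 = one random-walk
        doubling, the standard choice).
    prune_threshold
        Transition probabilities below this value are zeroed after inflation
        (columns are renormalized afterwards), keeping the matrix sparse.
    """

    inflation: float = 1.2
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iterations: int = 200
    convergence_tol: float = 1e-6

    def __post_init__(self) -> None:
        if not self.inflation > 1:
            raise ValueError("inflation must be > 1")
        if not 0 <= self.prune_threshold <= 1e-2:
            raise ValueError("prune_threshold must lie in [0, 1e-2]")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")


@dataclass
class ModulePartition:
    """Mapping gene -> module id, with an explicit unassigned pool.

    Module ids are positive integers; genes that belong to no module (e.g.
    singleton MCL clusters below ``min_module_size``) are tracked separately
    and carry the sentinel id 0 on disk.
    """

    assignments: dict[str, int]
    unassigned: set[str] = field(default_factory=set)
    converged: bool = True
    diagnostics: dict | None = None

    def __post_init__(self) -> None:
        overlap = set(self.assignments) & self.unassigned
        if overlap:
            raise ValueError(f"genes both assigned and unassigned: {sorted(overlap)[:5]}")

    @property
    def genes(self) -> set[str]:
        return set(self.assignments) | self.unassigned

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.assignments.values()))

    @property
    def module_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for m in self.assignments.values():
            sizes[m] = sizes.get(m, 0) + 1
        return sizes

    def genes_in(self, module_id: int) -> list[str]:
        return sorted(g for g, m in self.assignments.items() if m == module_id)

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, m) for g, m in self.assignments.items()]
        rows += [(g, UNASSIGNED) for g in self.unassigned]
        rows.sort()
        return pd.DataFrame(rows, columns=["gene", "module"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ModulePartition":
        df = pd.read_csv(path, sep="\t", dtype={"gene": str, "module": int})
        assigned = {r.gene: int(r.module) for r in df.itertuples() if r.module != UNASSIGNED}
        un = {r.gene for r in df.itertuples() if r.module == UNASSIGNED}
        return cls(assignments=assigned, unassigned=un)


def _adjacency(graph: nx.Graph) -> tuple[list[str], sp.csc_matrix]:
    """Weighted adjacency with MCL self-loops, columns normalized to sum 1.

    Nodes are sorted so the result is independent of edge insertion order.
    The self-loop weight is the maximum incident edge weight of the node
    (standard practice; guarantees aperiodic walks without overwhelming the
    neighbour flow), or 1.0 for an isolated node.
    """
    nodes = sorted(graph.nodes)
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    rows, cols, vals = [], [], []
    loop = np.zeros(n)
    for u, v, w in graph.edges(data="weight", default=1.0):
        if u == v:
            continue
        if w <= 0:
            raise ValueError(f"MCL requires positive edge weights, got {w} on ({u},{v})")
        i, j = index[u], index[v]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
        loop[i] = max(loop[i], w)
        loop[j] = max(loop[j], w)
    loop[loop == 0] = 1.0
    rows += list(range(n))
    cols += list(range(n))
    vals += list(loop)
    M = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    return nodes, _normalize_columns(M)


def _normalize_columns(M: sp.csc_matrix) -> sp.csc_matrix:
    sums = np.asarray(M.sum(axis=0)).ravel()
    sums[sums == 0] = 1.0
    return (M @ sp.diags(1.0 / sums)).tocsc()


def _inflate(M: sp.csc_matrix, inflation: float, prune: float) -> sp.csc_matrix:
    M = M.copy()
    M.data = np.power(M.data, inflation)
    if prune > 0:
        M.data[M.data < prune] = 0.0
        M.eliminate_zeros()
    return _normalize_columns(M)


def mcl_cluster(
    network,
    params: MCLParams | None = None,
    min_module_size: int = 2,
) -> ModulePartition:
    """Cluster a weighted network with the Markov Cluster algorithm.

    Parameters
    ----------
    network
        A ``networkx.Graph`` with positive ``weight`` edge attributes (|r|
        for co-expression networks), or any object with a ``graph``
        attribute holding one.
    params
        :class:`MCLParams`; defaults to inflation 1.2.
    min_module_size
        Clusters smaller than this are reported as unassigned genes.

    Returns
    -------
    ModulePartition
        Module ids numbered 1..C by decreasing size (ties broken by the
        smallest member gene id). ``diagnostics`` records per-iteration
        column-sum deviation and matrix change; ``converged`` is False if
        ``max_iterations`` was exhausted (a warning is emitted and the
        current matrix is interpreted as-is).
    """
    graph = network if isinstance(network, nx.Graph) else network.graph
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty network")
    params = params or MCLParams()

    nodes, M = _adjacency(graph)
    colsum_dev: list[float] = []
    changes: list[float] = []
    converged = False
    for _ in range(params.max_iterations):
        prev = M
        for _ in range(params.expansion - 1):
            M = (M @ M).tocsc()
        M = _inflate(M, params.inflation, params.prune_threshold)
        colsum_dev.append(float(np.abs(np.asarray(M.sum(axis=0)).ravel() - 1.0).max()))
        change = float(np.abs(M - prev).max()) if (M - prev).nnz else 0.0
        changes.append(change)
        if change < params.convergence_tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge within {params.max_iterations} iterations "
            f"(last change {changes[-1]:.2e}); interpreting current matrix",
            RuntimeWarning,
        )

    labels = _interpret(M)
    partition = _labels_to_partition(nodes, labels, min_module_size)
    partition.converged = converged
    partition.diagnostics = {
        "iterations": len(changes),
        "max_colsum_deviation": colsum_dev,
        "change": changes,
    }
    return partition


def _interpret(M: sp.csc_matrix) -> np.ndarray:
    """Read clusters from the attractor structure of the (near-)limit matrix.

    Attractors are nodes with positive return probability (non-zero
    diagonal). Attractors that attract a common node belong to one attractor
    system; every node joins the system holding its largest incoming flow,
    ties resolved toward the smallest system id.
    """
    n = M.shape[0]
    M = M.tocsr()
    diag = M.diagonal()
    attractors = np.flatnonzero(diag > 0)
    if attractors.size == 0:  # pathological non-converged state
        attractors = np.array([int(np.argmax(M[:, j].toarray())) for j in range(n)])
        attractors = np.unique(attractors)

    # union attractors sharing any attracted column
    parent = {int(a): int(a) for a in attractors}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    A = (M[attractors] > 0).astype(np.int8)
    overlap = A @ A.T  # attractor pairs sharing a column
    oi, oj = overlap.nonzero()
    for i, j in zip(attractors[oi], attractors[oj]):
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    system_of = {int(a): find(int(a)) for a in attractors}
    labels = np.full(n, -1, dtype=int)
    Mc = M.tocsc()
    for j in range(n):
        col = Mc.getcol(j)
        rows = col.indices
        vals = col.data
        cand = [(v, system_of[int(r)]) for r, v in zip(rows, vals) if int(r) in system_of]
        if not cand:
            continue
        best_v = max(v for v, _ in cand)
        labels[j] = min(s for v, s in cand if v >= best_v - 1e-12)
    return labels


def _labels_to_partition(nodes: list[str], labels: np.ndarray, min_module_size: int) -> ModulePartition:
    groups: dict[int, list[str]] = {}
    unassigned: set[str] = set()
    for g, lab in zip(nodes, labels):
        if lab < 0:
            unassigned.add(g)
        else:
            groups.setdefault(int(lab), []).append(g)
    kept = []
    for lab, members in groups.items():
        if len(members) >= min_module_size:
            kept.append(sorted(members))
        else:
            unassigned.update(members)
    # number modules by decreasing size, ties by smallest gene id
    kept.sort(key=lambda ms: (-len(ms), ms[0]))
    assignments = {g: i + 1 for i, members in enumerate(kept) for g in members}
    return ModulePartition(assignments=assignments, unassigned=unassigned)


def module_agreement(
    p1: ModulePartition, p2: ModulePartition
) -> tuple[pd.DataFrame, float]:
    """Cross-tabulate two partitions and score agreement by the adjusted Rand index.

    Agreement is computed over genes assigned to a module in *both*
    partitions. The ARI uses the standard permutation-model chance
    correction (1 = identical partitions, ~0 = chance-level agreement).
    """
    shared = sorted(set(p1.assignments) & set(p2.assignments))
    if not shared:
        raise ValueError("partitions share no assigned genes")
    a = [p1.assignments[g] for g in shared]
    b = [p2.assignments[g] for g in shared]
    table = pd.crosstab(
        pd.Series(a, name="partition_1"), pd.Series(b, name="partition_2")
    )
    ari = float(adjusted_rand_score(a, b))
    return table, ari
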