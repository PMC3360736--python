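"""Co-expression network construction with density-guided threshold selection.

The workflow mirrors value-based co-expression network building for large
microarray compendia: (1) absolute Pearson correlation between every pair of
responsive genes over the concatenated sample profile; (2) scan a grid of
correlation cutoffs and pick the one minimizing network *density* — the
ratio of realized edges to all possible edges among non-singleton nodes —
which marks the point where biologically meaningful co-expression separates
from background; (3) threshold at the selected cutoff and apply reciprocal
top-k pruning (keep an edge only if each endpoint ranks the other within its
k strongest correlations) so genes inside one tight module do not drag in
links to other modules; (4) summarize the degree distribution with a
power-law fit as a scale-free topology check.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .deg_screen import ExpressionSet

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Symmetric matrix of absolute Pearson correlations between gene profiles."""

    genes: list[str]
    values: np.ndarray  # n x n, |r|, diagonal 1 but ignored by all edge logic
    n_samples: int

    def __post_init__(self) -> None:
        n = len(self.genes)
        if self.values.shape != (n, n):
            raise ValueError("correlation matrix shape does not match gene list")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def offdiag_max(self) -> np.ndarray:
        v = self.values.copy()
        np.fill_diagonal(v, -np.inf)
        return v.max(axis=1)


def correlation_matrix(
    sets: Sequence[ExpressionSet],
    genes: Iterable[str] | None = None,
) -> CorrelationMatrix:
    """Absolute Pearson correlation over the concatenated sample profile.

    Profiles concatenate all samples of all experiment sets (N data points
    per gene), giving one network for the whole compendium. Genes with zero
    profile variance have undefined correlations and are dropped with a
    warning.
    """
    mats = [e.matrix for e in sets]
    common = mats[0].index
    for m in mats[1:]:
        common = common.intersection(m.index)
    if genes is not None:
        genes = [g for g in genes if g in set(common)]
    else:
        genes = list(common)
    profile = pd.concat([m.loc[genes] for m in mats], axis=1)
    X = profile.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 data points in the concatenated profile")
    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(genes, keep) if not k]
        logger.warning("dropping %d zero-variance genes: %s ...", len(dropped), dropped[:5])
        genes = [g for g, k in zip(genes, keep) if k]
        X = X[keep]
    R = np.abs(np.atleast_2d(np.corrcoef(X)))
    np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(genes=list(genes), values=R, n_samples=X.shape[1])


@dataclass
class DensityCurve:
    """Edge/node/density counts per cutoff and the density-minimum selection."""

    table: pd.DataFrame  # columns: cutoff, edges, nodes, possible, density
    selected_cutoff: float


def density_curve_and_cutoff(
    corr: CorrelationMatrix,
    grid: Sequence[float] | None = None,
) -> DensityCurve:
    """Scan cutoffs and select the density-minimizing correlation threshold.

    For each cutoff c the curve records E (pairs with r > c), K
    (non-singleton nodes, i.e. genes with at least one such edge), the
    possible edge count K(K-1)/2 and the density D = E / (K(K-1)/2), which
    is defined only when K >= 2. The selected cutoff is the grid argmin of
    D, ties broken toward the smaller cutoff; a minimum at the last grid
    point means the characteristic density upturn was never reached and is
    warned about.
    """
    if grid is None:
        grid = np.round(np.arange(0.50, 0.95 + 1e-9, 0.01), 2)
    grid = np.asarray(list(grid), dtype=float)
    if not np.all(np.diff(grid) > 0):
        raise ValueError("cutoff grid must be sorted ascending")

    iu = np.triu_indices(corr.n_genes, k=1)
    pair_r = np.sort(corr.values[iu])
    node_max = np.sort(corr.offdiag_max())
    n_pairs, n_nodes = pair_r.size, node_max.size

    rows = []
    for c in grid:
        E = n_pairs - np.searchsorted(pair_r, c, side="right")
        K = n_nodes - np.searchsorted(node_max, c, side="right")
        possible = K * (K - 1) // 2
        D = E / possible if K >= 2 else np.nan
        rows.append((c, int(E), int(K), int(possible), D))
    table = pd.DataFrame(rows, columns=["cutoff", "edges", "nodes", "possible", "density"])

    dens = table["density"].to_numpy()
    if np.all(np.isnan(dens)):
        raise ValueError("density undefined at every grid cutoff (fewer than 2 connected nodes)")
    idx = int(np.nanargmin(dens))  # first occurrence wins ties -> smaller cutoff
    selected = float(grid[idx])
    if idx == len(grid) - 1:
        warnings.warn(
            "density is minimal at the last grid point; the density minimum may lie "
            "beyond the grid (strictly decreasing curve)",
            RuntimeWarning,
        )
    return DensityCurve(table=table, selected_cutoff=selected)


@dataclass
class CoexpressionNetwork:
    """Thresholded, reciprocally pruned co-expression graph."""

    graph: nx.Graph
    cutoff: float
    k_limit: int
    summary: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [(u, v, w) if u <= v else (v, u, w)
                for u, v, w in self.graph.edges(data="weight")]
        rows.sort()
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r"])

    def to_edge_tsv(self, path) -> None:
        self.edge_table().to_csv(path, sep="\t", index=False)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_network(
    corr: CorrelationMatrix,
    cutoff: float,
    k_limit: int | str = "auto",
) -> CoexpressionNetwork:
    """Threshold the correlation matrix and prune by reciprocal top-k rank.

    Preliminary edges are all gene pairs with r > cutoff (strict). With
    ``k_limit="auto"`` the link limit is the preliminary network's average
    degree rounded half-up — the convention that ties the limit to the
    network's own connectivity scale. An edge (i, j) survives pruning only
    if j is among i's k strongest correlations *and* i is among j's; rank
    ties are broken by gene id so the result is deterministic and
    independent of node iteration order.
    """
    if not 0 < cutoff < 1:
        raise ValueError(f"cutoff must lie in (0, 1), got {cutoff}")
    R = corr.values
    n = corr.n_genes
    adj = R > cutoff
    np.fill_diagonal(adj, False)
    degrees = adj.sum(axis=1)
    n_pre_nodes = int((degrees > 0).sum())
    n_pre_edges = int(adj.sum()) // 2
    if n_pre_edges == 0:
        raise ValueError(f"no edges remain at cutoff {cutoff}; empty preliminary network")

    if k_limit == "auto":
        avg_degree = 2 * n_pre_edges / n_pre_nodes
        k = int(np.floor(avg_degree + 0.5))  # round half-up
    else:
        k = int(k_limit)
    if k < 1:
        raise ValueError("k_limit must be >= 1")

    order = np.argsort(np.array(corr.genes))  # lexicographic tie-break helper
    rank_key = np.empty(n, dtype=float)
    rank_key[order] = np.arange(n)

    top: list[set[int]] = []
    for i in range(n):
        nb = np.flatnonzero(adj[i])
        if nb.size > k:
            # strongest r first; ties by lexicographic gene id
            sel = nb[np.lexsort((rank_key[nb], -R[i, nb]))][:k]
        else:
            sel = nb
        top.append(set(int(j) for j in sel))

    graph = nx.Graph()
    for i in range(n):
        for j in top[i]:
            if j > i and i in top[j]:
                graph.add_edge(corr.genes[i], corr.genes[j], weight=float(R[i, j]))

    weights = [w for _, _, w in graph.edges(data="weight")]
    nn, ne = graph.number_of_nodes(), graph.number_of_edges()
    summary = {
        "preliminary_nodes": n_pre_nodes,
        "preliminary_edges": n_pre_edges,
        "preliminary_average_degree": 2 * n_pre_edges / n_pre_nodes,
        "n_nodes": nn,
        "n_edges": ne,
        "mean_edge_weight": float(np.mean(weights)) if weights else float("nan"),
        "average_degree": 2 * ne / nn if nn else 0.0,
    }
    logger.info(
        "network at cutoff %.3f: preliminary %d/%d, pruned (k=%d) %d nodes / %d edges",
        cutoff, n_pre_nodes, n_pre_edges, k, nn, ne,
    )
    return CoexpressionNetwork(graph=graph, cutoff=float(cutoff), k_limit=k, summary=summary)


@dataclass
class DegreeStats:
    histogram: dict[int, int]
    exponent: float | None
    r_squared: float | None


def fit_power_law(histogram: Mapping[int, int]) -> tuple[float | None, float | None]:
    """Least-squares slope of log10 P(k) vs log10 k over degrees with P(k) > 0."""
    ks = np.array(sorted(k for k, c in histogram.items() if k >= 1 and c > 0), dtype=float)
    if ks.size < 2:
        return None, None
    total = sum(c for k, c in histogram.items() if k >= 1 and c > 0)
    pk = np.array([histogram[int(k)] / total for k in ks])
    x, y = np.log10(ks), np.log10(pk)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = float(1 - np.sum(resid**2) / ss_tot) if ss_tot > 0 else None
    return float(slope), r2


def degree_stats(net: CoexpressionNetwork) -> DegreeStats:
    """Degree histogram plus a power-law (scale-free) fit of P(k).

    With fewer than two distinct degrees the exponent is undefined and
    reported as None (e.g. a complete graph).
    """
    if net.n_nodes < 10:
        raise ValueError("degree statistics require at least 10 nodes")
    hist: dict[int, int] = {}
    for _, d in net.graph.degree():
        hist[d] = hist.get(d, 0) + 1
    exponent, r2 = fit_power_law(hist)
    return DegreeStats(histogram=dict(sorted(hist.items())), exponent=exponent, r_squared=r2)
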