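"""Thresholded Pearson coexpression graphs and Markov clustering.

MCL is implemented in-repo: starting from a column-stochastic matrix built
from the edge weights (self-loops set to each node's maximum incident
weight), the iteration alternates expansion (matrix squaring) with inflation
(entrywise power followed by column renormalization), pruning tiny entries,
until the iterate stops changing. Clusters are read off the converged
matrix: attractor rows (non-zero diagonal) span the nodes they reach;
attractors with overlapping span are merged so the result is a disjoint
partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ExpressionTable
from .errors import AnalysisError

log = logging.getLogger(__name__)


@dataclass
class CoexpressionGraph:
    """Undirected weighted graph of profiles correlated above a threshold."""

    graph: nx.Graph
    threshold_r: float

    @property
    def node_ids(self) -> list:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list:
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]


@dataclass
class ClusterSet:
    """Disjoint clusters ordered by size (descending, ties by smallest
    member id); indices start at 0."""

    clusters: list
    inflation: float
    min_cluster_size: int = 3
    unclustered: list = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set = set()
        for members in self.clusters:
            overlap = seen & set(members)
            if overlap:
                raise AnalysisError(f"clusters overlap on {sorted(overlap)[:5]}")
            seen |= set(members)

    def __len__(self) -> int:
        return len(self.clusters)

    def labels(self) -> pd.Series:
        """Per-feature cluster index (unclustered features absent)."""
        data = {m: i for i, members in enumerate(self.clusters) for m in members}
        return pd.Series(data, name="cluster_id").sort_index()


def pearson_graph(
    profiles: ExpressionTable,
    threshold_r: float,
    log2p1: bool = False,
    binary_weights: bool = False,
) -> CoexpressionGraph:
    """All-pairs Pearson correlation of profiles, keeping edges with
    r >= ``threshold_r``. Zero-variance profiles are dropped with a warning
    (the upstream CV filter should already have removed them).

    ``log2p1`` correlates log2(TPM+1) instead of raw TPM; ``binary_weights``
    stores weight 1 on every retained edge (else the correlation itself).
    """
    data = profiles.data
    if log2p1:
        data = np.log2(data + 1.0)
    sd = data.std(axis=1, ddof=0)
    degenerate = sd[sd == 0].index.tolist()
    if degenerate:
        log.warning(
            "%d zero-variance profiles dropped from the correlation graph",
            len(degenerate),
        )
        data = data.drop(index=degenerate)
    nodes = data.index.tolist()
    g = nx.Graph()
    g.add_nodes_from(nodes)
    if len(nodes) >= 2:
        r = np.corrcoef(data.to_numpy())
        iu, ju = np.triu_indices(len(nodes), k=1)
        keep = r[iu, ju] >= threshold_r
        g.add_weighted_edges_from(
            (nodes[i], nodes[j], 1.0 if binary_weights else float(r[i, j]))
            for i, j in zip(iu[keep], ju[keep])
        )
    return CoexpressionGraph(g, threshold_r)


class MarkovClustering:
    """MCL graph clustering.

    Parameters
    ----------
    inflation : float, default 1.6
        Entrywise power applied after each expansion; larger values give
        finer clusters.
    min_cluster_size : int, default 3
        Converged components smaller than this are reported as unclustered.
    prune_threshold : float, default 1e-5
        Entries below this are zeroed (then columns renormalized) after each
        inflation, the standard sparsity heuristic.
    tol : float, default 1e-8
        Convergence: max absolute change of the iterate between rounds.
    max_iter : int, default 200

    Attributes
    ----------
    clusters_ : ClusterSet
    labels_ : Series mapping node id -> cluster index (clustered nodes only)
    n_iter_ : int
    converged_ : bool
    """

    def __init__(
        self,
        inflation: float = 1.6,
        min_cluster_size: int = 3,
        prune_threshold: float = 1e-5,
        tol: float = 1e-8,
        max_iter: int = 200,
    ):
        self.inflation = inflation
        self.min_cluster_size = min_cluster_size
        self.prune_threshold = prune_threshold
        self.tol = tol
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {
            "inflation": self.inflation,
            "min_cluster_size": self.min_cluster_size,
            "prune_threshold": self.prune_threshold,
            "tol": self.tol,
            "max_iter": self.max_iter,
        }

    def set_params(self, **params) -> "MarkovClustering":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _normalize(m: np.ndarray) -> np.ndarray:
        sums = m.sum(axis=0, keepdims=True)
        sums[sums == 0] = 1.0
        return m / sums

    def _iterate(self, m: np.ndarray) -> tuple[np.ndarray, int, bool]:
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            prev = m
            m = m @ m                                  # expansion
            m = self._normalize(m ** self.inflation)   # inflation
            m[m < self.prune_threshold] = 0.0          # pruning
            m = self._normalize(m)
            if np.max(np.abs(m - prev)) < self.tol:
                converged = True
                break
        return m, it, converged

    def fit(self, graph) -> "MarkovClustering":
        """Cluster a CoexpressionGraph, networkx Graph, or a symmetric
        non-negative adjacency matrix (optionally a DataFrame)."""
        if isinstance(graph, CoexpressionGraph):
            graph = graph.graph
        if isinstance(graph, nx.Graph):
            nodes = list(graph.nodes)
            a = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
        elif isinstance(graph, pd.DataFrame):
            nodes = graph.index.tolist()
            a = graph.to_numpy(dtype=float)
        else:
            a = np.asarray(graph, dtype=float)
            nodes = list(range(a.shape[0]))
        if a.size == 0:
            raise AnalysisError("cannot cluster an empty graph")
        if a.shape[0] != a.shape[1]:
            raise AnalysisError("adjacency matrix must be square")

        a = a.copy()
        np.fill_diagonal(a, 0.0)
        # self-loop = max incident edge weight (1 for isolated nodes) so
        # every column is a proper distribution and singletons are stable
        loops = a.max(axis=0)
        loops[loops <= 0] = 1.0
        np.fill_diagonal(a, loops)

        m, n_iter, converged = self._iterate(self._normalize(a))
        if not converged:
            log.warning(
                "MCL did not converge in %d iterations; clusters taken from "
                "the last iterate", self.max_iter,
            )

        raw = extract_clusters(m)
        clusters, unclustered = [], []
        for comp in raw:
            members = sorted(nodes[i] for i in comp)
            if len(members) >= self.min_cluster_size:
                clusters.append(members)
            else:
                unclustered.extend(members)
        clusters.sort(key=lambda ms: (-len(ms), ms[0]))

        self.clusters_ = ClusterSet(
            clusters, self.inflation, self.min_cluster_size, sorted(unclustered)
        )
        self.labels_ = self.clusters_.labels()
        self.n_iter_ = n_iter
        self.converged_ = converged
        return self

    def fit_predict(self, graph) -> pd.Series:
        return self.fit(graph).labels_


def extract_clusters(m: np.ndarray, eps: float = 1e-9) -> list:
    """Read clusters off a converged MCL iterate.

    Attractors are rows with non-negligible diagonal mass; each attractor
    row spans the columns it reaches, and attractors with overlapping span
    are merged (weakly connected components of the support restricted to
    attractor rows). Nodes reached by no attractor become singletons.
    Returns a list of lists of integer node indices.
    """
    n = m.shape[0]
    attractors = np.flatnonzero(np.diag(m) > eps)
    support = [set(np.flatnonzero(m[i] > eps)) | {i} for i in attractors]

    merged: list[set] = []
    for s in support:
        hits = [c for c in merged if c & s]
        for c in hits:
            merged.remove(c)
            s = s | c
        merged.append(s)

    covered = set().union(*merged) if merged else set()
    for i in range(n):
        if i not in covered:
            merged.append({i})
    return [sorted(c) for c in merged]


def mcl_cluster(
    graph, inflation: float = 1.6, min_cluster_size: int = 3, **kwargs
) -> ClusterSet:
    """Functional wrapper around :class:`MarkovClustering`."""
    model = MarkovClustering(
        inflation=inflation, min_cluster_size=min_cluster_size, **kwargs
    )
    return model.fit(graph).clusters_


def sample_network(
    gene_table: ExpressionTable,
    threshold_r: float = 0.95,
    inflation: float = 2.2,
    min_cluster_size: int = 2,
) -> tuple[CoexpressionGraph, ClusterSet]:
    """Sample-to-sample correlation network over gene-level expression
    (nodes are samples/timepoints), clustered with MCL."""
    if len(gene_table.data) < 3:
        raise AnalysisError("sample network needs at least 3 genes")
    transposed = ExpressionTable(gene_table.data.T, gene_table.unit)
    graph = pearson_graph(transposed, threshold_r)
    clusters = mcl_cluster(graph, inflation, min_cluster_size=min_cluster_size)
    return graph, clusters


def cluster_profiles(
    clusters: ClusterSet, profiles: ExpressionTable
) -> ExpressionTable:
    """Mean profile per cluster (row ``cluster<k>`` for the k-th cluster)."""
    rows, idx = [], []
    for k, members in enumerate(clusters.clusters):
        present = [m for m in members if m in profiles.data.index]
        if not present:
            continue
        rows.append(profiles.data.loc[present].mean(axis=0))
        idx.append(f"cluster{k}")
    frame = (
        pd.DataFrame(rows, index=idx)
        if rows
        else pd.DataFrame(columns=profiles.data.columns)
    )
    return ExpressionTable(frame, profiles.unit)
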