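"""Constraint-based causal structure learning and key driver analysis.

The PC algorithm learns a completed partially directed acyclic graph
(CPDAG) over gene expression profiles: starting from the complete
undirected graph, edges are deleted whenever a conditional independence
test accepts, using Gaussian partial-correlation tests (Fisher z) at
significance level alpha; v-structures are then oriented from the
recorded separation sets and Meek rules propagate further orientations.
The order-independent ("stable") variant snapshots adjacency sets per
level so the output does not depend on variable ordering.

Key driver analysis (KDA) ranks nodes of the module subnetwork by the
size mu of their h-layer downstream neighborhood (HLN, nodes reachable
through directed edges in at most h steps): nodes with mu above
mean + 1 sd are causal regulators, and regulators with out-degree above
mean + 2 sd are key drivers. Undirected CPDAG edges are never traversed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "CausalGraph",
    "KdaResult",
    "partial_correlation",
    "ci_test_gauss",
    "pc_skeleton",
    "orient_edges",
    "hln_size",
    "key_driver_analysis",
    "PCAlgorithm",
]


@dataclass
class CausalGraph:
    """Partially directed graph with separation sets."""

    nodes: list
    directed: set = field(default_factory=set)     # (from, to)
    undirected: set = field(default_factory=set)   # frozenset({a, b})
    sepsets: dict = field(default_factory=dict)    # (a, b) -> frozenset

    def has_edge(self, a, b) -> bool:
        return (
            (a, b) in self.directed
            or (b, a) in self.directed
            or frozenset((a, b)) in self.undirected
        )

    def neighbors(self, a) -> set:
        out = {v for (u, v) in self.directed if u == a}
        out |= {u for (u, v) in self.directed if v == a}
        out |= {next(iter(e - {a})) for e in self.undirected if a in e}
        return out

    def successors(self, a) -> set:
        return {v for (u, v) in self.directed if u == a}

    def out_degree(self, a) -> int:
        return len(self.successors(a))

    def to_networkx(self) -> nx.DiGraph:
        """Directed edges as arcs; undirected edges as reciprocal arcs
        tagged ``kind='undirected'``."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for u, v in self.directed:
            g.add_edge(u, v, kind="directed")
        for e in self.undirected:
            a, b = sorted(e)
            g.add_edge(a, b, kind="undirected")
            g.add_edge(b, a, kind="undirected")
        return g

    def edge_list(self) -> pd.DataFrame:
        rows = [(u, v, "directed") for u, v in sorted(self.directed)]
        rows += [
            (*sorted(e), "undirected") for e in self.undirected
        ]
        return pd.DataFrame(rows, columns=["from", "to", "type"]).sort_values(
            ["type", "from", "to"], ignore_index=True
        )


def partial_correlation(corr: np.ndarray, i: int, j: int, s) -> float:
    """Partial correlation of variables i and j given the index set s,
    from the inverse of the correlation submatrix."""
    s = list(s)
    idx = [i, j] + s
    sub = np.asarray(corr)[np.ix_(idx, idx)]
    try:
        prec = np.linalg.inv(sub)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            f"singular correlation submatrix for ({i},{j}|{s})"
        ) from err
    return float(-prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1]))


def ci_test_gauss(
    r_partial: float, n: int, s_size: int, alpha: float = 0.01
) -> tuple[float, bool]:
    """Fisher-z test of zero partial correlation.

    Statistic sqrt(n - |S| - 3) * |arctanh(r)| against the standard
    normal, two-sided. Returns ``(p, reject)`` with rejection at
    p < alpha.
    """
    df = n - s_size - 3
    if df <= 0:
        raise ValueError(f"n - |S| - 3 = {df} must be positive")
    if abs(r_partial) >= 1.0:
        warnings.warn("|partial correlation| >= 1; p set to 0")
        return 0.0, True
    z = 0.5 * np.log((1 + r_partial) / (1 - r_partial))
    stat = np.sqrt(df) * abs(z)
    p = 2.0 * stats.norm.sf(stat)
    return float(p), bool(p < alpha)


def pc_skeleton(
    expr: pd.DataFrame, alpha: float = 0.01, max_cond_size: int | None = None
) -> CausalGraph:
    """Order-independent PC skeleton over genes (rows) of ``expr``.

    Level ell = 0, 1, 2, ... removes the edge (i, j) when some subset S
    of the level-start adjacency of i (excluding j), |S| = ell, gives a
    non-rejected Gaussian CI test; S is recorded as the separation set
    of both orders. Nodes and candidate sets iterate in sorted-id order,
    making the result deterministic and invariant to input row order.
    """
    x = expr.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("expression contains non-finite values")
    order = np.argsort(expr.index)
    genes = [expr.index[k] for k in order]
    corr = np.corrcoef(x[order])
    n = expr.shape[1]
    p = len(genes)
    pos = {g: k for k, g in enumerate(genes)}
    graph = CausalGraph(nodes=list(genes))
    graph.undirected = {
        frozenset((genes[a], genes[b]))
        for a in range(p)
        for b in range(a + 1, p)
    }
    ell = 0
    while True:
        if n - ell - 3 <= 0:
            break
        if max_cond_size is not None and ell > max_cond_size:
            break
        adj_snapshot = {g: sorted(graph.neighbors(g)) for g in genes}
        if all(len(adj_snapshot[g]) - 1 < ell for g in genes):
            break
        for a in genes:
            for b in adj_snapshot[a]:
                if not graph.has_edge(a, b):
                    continue
                candidates = [v for v in adj_snapshot[a] if v != b]
                if len(candidates) < ell:
                    continue
                for s in itertools.combinations(candidates, ell):
                    r = partial_correlation(
                        corr, pos[a], pos[b], [pos[v] for v in s]
                    )
                    _, reject = ci_test_gauss(r, n, ell, alpha)
                    if not reject:
                        graph.undirected.discard(frozenset((a, b)))
                        graph.sepsets[(a, b)] = frozenset(s)
                        graph.sepsets[(b, a)] = frozenset(s)
                        break
        ell += 1
    return graph


def _meek_rules(graph: CausalGraph) -> None:
    """Apply Meek rules 1-3 to closure, in sorted deterministic order."""
    changed = True
    while changed:
        changed = False
        for e in sorted(graph.undirected, key=sorted):
            a, b = sorted(e)
            for x, y in ((a, b), (b, a)):
                # R1: z -> x, x - y, z and y nonadjacent  =>  x -> y
                r1 = any(
                    (z, x) in graph.directed and not graph.has_edge(z, y)
                    for z in sorted(graph.nodes)
                    if z not in (x, y)
                )
                # R2: x -> z -> y and x - y  =>  x -> y
                r2 = any(
                    (x, z) in graph.directed and (z, y) in graph.directed
                    for z in sorted(graph.nodes)
                    if z not in (x, y)
                )
                # R3: x - z1 -> y, x - z2 -> y, z1 and z2 nonadjacent
                r3 = False
                partners = [
                    z
                    for z in sorted(graph.nodes)
                    if z not in (x, y)
                    and frozenset((x, z)) in graph.undirected
                    and (z, y) in graph.directed
                ]
                for z1, z2 in itertools.combinations(partners, 2):
                    if not graph.has_edge(z1, z2):
                        r3 = True
                        break
                if r1 or r2 or r3:
                    graph.undirected.discard(e)
                    graph.directed.add((x, y))
                    changed = True
                    break
    return None


def orient_edges(skeleton: CausalGraph) -> CausalGraph:
    """CPDAG orientation: v-structures from separation sets, then Meek
    rules 1-3 to closure.

    For every nonadjacent pair (i, j) with a common neighbor k not in
    sepset(i, j), orient i -> k <- j. Conflicting v-structure demands
    are resolved first-come in sorted order (the earlier orientation is
    kept), which keeps the output deterministic.
    """
    graph = CausalGraph(
        nodes=list(skeleton.nodes),
        directed=set(skeleton.directed),
        undirected=set(skeleton.undirected),
        sepsets=dict(skeleton.sepsets),
    )
    nodes = sorted(graph.nodes)
    for i, j in itertools.combinations(nodes, 2):
        if graph.has_edge(i, j):
            continue
        sep = graph.sepsets.get((i, j), frozenset())
        for k in nodes:
            if k in (i, j) or k in sep:
                continue
            if graph.has_edge(i, k) and graph.has_edge(j, k):
                for a in (i, j):
                    e = frozenset((a, k))
                    if e in graph.undirected and (k, a) not in graph.directed:
                        graph.undirected.discard(e)
                        graph.directed.add((a, k))
    _meek_rules(graph)
    return graph


def hln_size(graph: CausalGraph, node, h: int) -> int:
    """Nodes reachable from ``node`` via directed edges in <= h steps
    (the node itself excluded); undirected edges are not traversed."""
    if h < 1:
        raise ValueError("h must be >= 1")
    frontier = {node}
    seen: set = set()
    for _ in range(h):
        frontier = {
            v for u in frontier for v in graph.successors(u)
        } - seen - {node}
        if not frontier:
            break
        seen |= frontier
    return len(seen)


@dataclass
class KdaResult:
    mu: pd.Series                 # HLN size per node
    degree: pd.Series             # out-degree per node
    mu_threshold: float
    degree_threshold: float
    causal_regulators: set
    key_drivers: set


def key_driver_analysis(
    graph: CausalGraph, module_genes, h: int = 3
) -> KdaResult:
    """Key drivers of a module within a causal network.

    The graph is restricted to the module intersection; every node gets
    its h-layer downstream neighborhood size mu and its out-degree d.
    Causal regulators satisfy mu > mean(mu) + sd(mu); key drivers are
    regulators with d > mean(d) + 2 sd(d) (sample sd, n - 1).
    """
    module = set(module_genes)
    missing = module - set(graph.nodes)
    if missing:
        warnings.warn(
            f"{len(missing)} module gene(s) absent from the causal "
            f"network and dropped: {sorted(missing)[:5]}"
        )
    keep = sorted(module & set(graph.nodes))
    if len(keep) < 3:
        raise ValueError("module subnetwork has fewer than 3 nodes")
    sub = CausalGraph(
        nodes=keep,
        directed={
            (u, v) for (u, v) in graph.directed if u in module and v in module
        },
        undirected={
            e for e in graph.undirected if e <= module
        },
    )
    mu = pd.Series({v: hln_size(sub, v, h) for v in keep}, dtype=float)
    d = pd.Series({v: sub.out_degree(v) for v in keep}, dtype=float)
    mu_thr = float(mu.mean() + mu.std(ddof=1))
    d_thr = float(d.mean() + 2.0 * d.std(ddof=1))
    regulators = set(mu.index[mu > mu_thr])
    drivers = {v for v in regulators if d[v] > d_thr}
    return KdaResult(
        mu=mu,
        degree=d,
        mu_threshold=mu_thr,
        degree_threshold=d_thr,
        causal_regulators=regulators,
        key_drivers=drivers,
    )


class PCAlgorithm(BaseEstimator):
    """PC causal discovery as a scikit-learn-style estimator.

    ``fit`` takes a genes x samples DataFrame and exposes the learned
    CPDAG as ``graph_`` (a :class:`CausalGraph`) plus ``skeleton_``.
    """

    def __init__(self, alpha: float = 0.01, max_cond_size: int | None = None):
        self.alpha = alpha
        self.max_cond_size = max_cond_size

    def fit(self, X: pd.DataFrame, y=None):
        self.skeleton_ = pc_skeleton(X, self.alpha, self.max_cond_size)
        self.graph_ = orient_edges(self.skeleton_)
        return self

    def key_drivers(self, module_genes, h: int = 3) -> KdaResult:
        return key_driver_analysis(self.graph_, module_genes, h=h)
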