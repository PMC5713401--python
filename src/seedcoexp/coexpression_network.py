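"""Pearson coexpression networks over stage profiles and their decomposition
into connected subnetworks.

At the scale this pipeline targets (tens of thousands of genes, a handful of
stages) all-pairs correlation via centered matrix products is exact and fast;
no approximate shortcuts are used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .io_formats import ExpressionMatrix


class ConstantProfileError(ValueError):
    """Correlation against a constant profile is undefined; callers must
    handle the flag explicitly instead of receiving a silent 0."""


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length stage profiles,
    clamped to [-1, 1] against floating-point rounding."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 stages for a meaningful r")
    xc = x - x.mean()
    yc = y - y.mean()
    nx_ = float(np.sqrt(xc @ xc))
    ny_ = float(np.sqrt(yc @ yc))
    if nx_ == 0.0 or ny_ == 0.0:
        raise ConstantProfileError("correlation with a constant profile "
                                   "is undefined")
    return float(np.clip((xc @ yc) / (nx_ * ny_), -1.0, 1.0))


def correlation_matrix(m: ExpressionMatrix
                       ) -> tuple[tuple[str, ...], np.ndarray,
                                  frozenset[str]]:
    """All-pairs Pearson matrix over the matrix rows.

    Returns (gene order, symmetric matrix with unit diagonal, flagged
    constant genes). Constant genes are excluded from the matrix.
    """
    values = m.values
    sds = values.std(axis=1)
    constant = sds == 0
    kept = [g for g, c in zip(m.gene_ids, constant) if not c]
    v = values[~constant]
    centered = v - v.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    unit = centered / norms[:, None]
    corr = unit @ unit.T
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    return (tuple(kept), corr,
            frozenset(g for g, c in zip(m.gene_ids, constant) if c))


@dataclass(frozen=True)
class CoexpressionEdge:
    """Undirected coexpression edge; endpoints stored in lexicographic
    order, the signed r that created the edge retained."""

    gene_a: str
    gene_b: str
    r: float

    def __init__(self, gene_a: str, gene_b: str, r: float) -> None:
        a, b = sorted((str(gene_a), str(gene_b)))
        if a == b:
            raise ValueError(f"self-edge on {a!r}")
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"r={r} outside [-1, 1]")
        object.__setattr__(self, "gene_a", a)
        object.__setattr__(self, "gene_b", b)
        object.__setattr__(self, "r", float(r))

    @property
    def sign(self) -> str:
        return classify_edge_sign(self.r)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def classify_edge_sign(r: float) -> str:
    """positive iff r > 0. r == 0 cannot occur above any build threshold but
    is guarded anyway."""
    if r == 0:
        raise ValueError("sign of r = 0 is undefined")
    return "positive" if r > 0 else "negative"


@dataclass(frozen=True)
class CoexpressionNetwork:
    """Simple undirected graph on gene ids; every edge carries the Pearson r
    that created it and satisfies the build threshold/mode rule."""

    nodes: frozenset[str]
    edges: tuple[CoexpressionEdge, ...]
    build_threshold: float
    threshold_mode: str = "absolute"

    def __init__(self, nodes: Iterable[str], edges: Iterable[CoexpressionEdge],
                 build_threshold: float, threshold_mode: str = "absolute"
                 ) -> None:
        object.__setattr__(self, "nodes", frozenset(str(n) for n in nodes))
        object.__setattr__(self, "edges", tuple(edges))
        object.__setattr__(self, "build_threshold", float(build_threshold))
        object.__setattr__(self, "threshold_mode", threshold_mode)
        self._validate()

    def _validate(self) -> None:
        if self.threshold_mode not in ("absolute", "positive_only"):
            raise ValueError("threshold_mode must be absolute or "
                             "positive_only")
        seen = set()
        for e in self.edges:
            if e.pair in seen:
                raise ValueError(f"duplicate edge {e.pair}")
            seen.add(e.pair)
            if not {e.gene_a, e.gene_b} <= self.nodes:
                raise ValueError(f"edge {e.pair} references unknown node")
            stat = abs(e.r) if self.threshold_mode == "absolute" else e.r
            if not stat > self.build_threshold:
                raise ValueError(
                    f"edge {e.pair} (r={e.r}) violates "
                    f"{self.threshold_mode} threshold {self.build_threshold}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_r(self) -> dict[tuple[str, str], float]:
        return {e.pair: e.r for e in self.edges}

    def to_networkx(self) -> nx.Graph:
        graph = nx.Graph()
        graph.add_nodes_from(sorted(self.nodes))
        for e in sorted(self.edges, key=lambda e: e.pair):
            graph.add_edge(e.gene_a, e.gene_b, r=e.r, sign=e.sign)
        return graph


def build_network(m: ExpressionMatrix, threshold: float = 0.95,
                  mode: str = "absolute",
                  include_isolated: bool = False) -> CoexpressionNetwork:
    """Threshold the all-pairs correlation matrix into a graph.

    absolute mode keeps |r| > threshold (the default: published negative-r
    partners are reported as coexpressed too); positive_only keeps
    r > threshold. Nodes without surviving edges are kept only when
    ``include_isolated`` is set.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if mode not in ("absolute", "positive_only"):
        raise ValueError("mode must be absolute or positive_only")
    genes, corr, _constant = correlation_matrix(m)
    stat = np.abs(corr) if mode == "absolute" else corr
    ii, jj = np.nonzero(np.triu(stat > threshold, k=1))
    edges = [CoexpressionEdge(genes[i], genes[j], corr[i, j])
             for i, j in zip(ii.tolist(), jj.tolist())]
    if include_isolated:
        nodes: Iterable[str] = genes
    else:
        nodes = {n for e in edges for n in (e.gene_a, e.gene_b)}
    return CoexpressionNetwork(nodes, edges, threshold, mode)


@dataclass(frozen=True)
class SubnetworkPartition:
    """Connected components ordered by decreasing size (ties broken by the
    lexicographically smallest member), plus per-node degrees."""

    components: tuple[frozenset[str], ...]
    degrees: Mapping[str, int] = field(default_factory=dict)

    def sizes(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.components)

    def component_of(self) -> dict[str, int]:
        """gene -> 0-based component rank."""
        return {g: i for i, comp in enumerate(self.components) for g in comp}


def connected_components(net: CoexpressionNetwork) -> SubnetworkPartition:
    """Maximal connected components of the network; isolated nodes become
    singletons."""
    graph = net.to_networkx()
    comps = [frozenset(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return SubnetworkPartition(tuple(comps), node_degrees(net))


def node_degrees(net: CoexpressionNetwork) -> dict[str, int]:
    degrees = {n: 0 for n in net.nodes}
    for e in net.edges:
        degrees[e.gene_a] += 1
        degrees[e.gene_b] += 1
    return degrees


@dataclass(frozen=True)
class SubnetworkSummary:
    rank: int
    members: frozenset[str]
    size: int
    mean_abs_r: float
    hub_gene: str
    hub_degree: int


def main_subnetworks(net: CoexpressionNetwork, k: int = 2,
                     partition: SubnetworkPartition | None = None
                     ) -> tuple[list[SubnetworkSummary], frozenset[str]]:
    """The k largest components with summary statistics, plus the residual
    gene set (members of the remaining, smaller components)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if partition is None:
        partition = connected_components(net)
    if k > len(partition.components):
        warnings.warn(f"requested {k} subnetworks but only "
                      f"{len(partition.components)} components exist",
                      stacklevel=2)
        k = len(partition.components)
    degrees = node_degrees(net)
    summaries = []
    for rank, comp in enumerate(partition.components[:k], start=1):
        rs = [abs(e.r) for e in net.edges
              if e.gene_a in comp and e.gene_b in comp]
        hub = max(sorted(comp), key=lambda g: degrees.get(g, 0))
        summaries.append(SubnetworkSummary(
            rank=rank, members=comp, size=len(comp),
            mean_abs_r=float(np.mean(rs)) if rs else float("nan"),
            hub_gene=hub, hub_degree=degrees.get(hub, 0)))
    residual = frozenset().union(*partition.components[k:]) \
        if len(partition.components) > k else frozenset()
    return summaries, residual
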