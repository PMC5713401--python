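"""Guide-gene queries: extract every gene coexpressed with a designated
guide above threshold, overlay TF-family annotation and summarize family
distributions.

The query runs transcriptome-wide on the filtered matrix (not on any
pathway-restricted subnetwork). A soft prefilter (default |r| > 0.6)
precedes the report threshold (default |r| > 0.95); since the final
threshold is at least as strict, the prefilter never changes results and
exists only to bound the candidate set.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .coexpression_network import (
    CoexpressionEdge,
    CoexpressionNetwork,
    ConstantProfileError,
    classify_edge_sign,
)
from .io_formats import AnnotationTable, ExpressionMatrix, PipelineConfig


@dataclass(frozen=True)
class GuideNeighbor:
    gene_id: str
    r: float
    sign: str
    tf_families: frozenset[str]


@dataclass(frozen=True)
class GuideQueryResult:
    """Above-threshold correlation partners of one guide gene, sorted by
    |r| descending (ties by gene id)."""

    guide_id: str
    neighbors: tuple[GuideNeighbor, ...]
    threshold_used: float
    prefilter_used: float

    def neighbor_ids(self) -> frozenset[str]:
        return frozenset(n.gene_id for n in self.neighbors)


def guide_query(m: ExpressionMatrix, guides: Sequence[str],
                ann: AnnotationTable | None = None,
                config: PipelineConfig | None = None,
                restrict_namespace: str | None = None
                ) -> list[GuideQueryResult]:
    """Two-stage screen per guide: candidates must pass
    |r| > prefilter_threshold, reported neighbors must pass the mode/threshold
    rule (default |r| > correlation_threshold).

    ``restrict_namespace`` limits neighbors to genes annotated in that
    namespace (e.g. ``tf_family`` for a TF-only search).
    """
    config = config or PipelineConfig()
    ann = ann or AnnotationTable()
    index = {g: i for i, g in enumerate(m.gene_ids)}
    missing = [g for g in guides if g not in index]
    if missing:
        raise KeyError(f"guide gene(s) not in matrix: {missing}")

    values = m.values
    sds = values.std(axis=1)
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)

    results = []
    for guide in guides:
        gi = index[guide]
        if sds[gi] == 0:
            raise ConstantProfileError(
                f"guide {guide!r} has a constant profile")
        gvec = centered[gi]
        with np.errstate(divide="ignore", invalid="ignore"):
            r_all = centered @ gvec / (norms * norms[gi])
        r_all = np.clip(r_all, -1.0, 1.0)
        r_all[norms == 0] = np.nan  # constant genes: undefined, never 0

        candidates = np.abs(r_all) > config.prefilter_threshold
        if config.threshold_mode == "absolute":
            passing = np.abs(r_all) > config.correlation_threshold
        else:
            passing = r_all > config.correlation_threshold
        passing &= candidates
        passing[gi] = False
        with np.errstate(invalid="ignore"):
            passing &= ~np.isnan(r_all)

        neighbors = []
        for j in np.nonzero(passing)[0].tolist():
            gene = m.gene_ids[j]
            if restrict_namespace is not None and not ann.is_annotated(
                    gene, restrict_namespace):
                continue
            r = float(r_all[j])
            neighbors.append(GuideNeighbor(
                gene_id=gene, r=r, sign=classify_edge_sign(r),
                tf_families=ann.tf_families(gene)))
        neighbors.sort(key=lambda n: (-abs(n.r), n.gene_id))
        results.append(GuideQueryResult(
            guide_id=guide, neighbors=tuple(neighbors),
            threshold_used=config.correlation_threshold,
            prefilter_used=config.prefilter_threshold))
    return results


@dataclass(frozen=True)
class FamilyDistribution:
    """Per-TF-family counts over a gene set. Genes carrying several family
    labels contribute one count per family and are flagged."""

    counts: Mapping[str, int]
    total_tf_count: int
    n_unannotated: int
    multi_family_genes: frozenset[str]

    def top(self, k: int) -> list[tuple[str, int]]:
        return sorted(self.counts.items(),
                      key=lambda kv: (-kv[1], kv[0]))[:k]


def family_distribution(genes: Iterable[str],
                        ann: AnnotationTable) -> FamilyDistribution:
    counts: Counter[str] = Counter()
    multi = set()
    n_unannotated = 0
    n_tf = 0
    for gene in genes:
        families = ann.tf_families(gene)
        if not families:
            n_unannotated += 1
            continue
        n_tf += 1
        if len(families) > 1:
            multi.add(gene)
        counts.update(families)
    return FamilyDistribution(dict(counts), n_tf, n_unannotated,
                              frozenset(multi))


def merge_guide_networks(results: Sequence[GuideQueryResult]
                         ) -> CoexpressionNetwork:
    """Star-union graph: guides as hubs, one guide-neighbor edge per query
    hit. A neighbor shared by two guides appears once as a node with one
    edge per guide."""
    if not results:
        raise ValueError("no guide query results to merge")
    thresholds = {r.threshold_used for r in results}
    if len(thresholds) > 1:
        raise ValueError("guide results were built at different thresholds")
    threshold = thresholds.pop()
    nodes = set()
    edges = []
    seen_pairs = set()
    for res in results:
        nodes.add(res.guide_id)
        for nb in res.neighbors:
            nodes.add(nb.gene_id)
            edge = CoexpressionEdge(res.guide_id, nb.gene_id, nb.r)
            if edge.pair not in seen_pairs:
                seen_pairs.add(edge.pair)
                edges.append(edge)
    return CoexpressionNetwork(nodes, edges, threshold, "absolute")
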