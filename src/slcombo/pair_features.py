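"""Per-gene-pair features for synthetic-lethality inference.

A candidate gene pair is described by three kinds of evidence:

* **annotation overlap** — the Dice coefficient ``2|A∩B| / (|A|+|B|)`` of the
  two genes' term sets, computed separately per annotation namespace
  (pathway memberships, ontology terms, disease associations, drug
  associations, ...);
* **node prominence** — the arithmetic mean over the two endpoints of
  node-based graph measures on an undirected interaction network: degree,
  normalised betweenness centrality, clustering coefficient and closeness
  centrality;
* **proximity** — the unweighted shortest-path length between the endpoints,
  with a finite sentinel (number of nodes + 1) and a ``connected`` flag when
  no path exists.

Genes missing from a corpus contribute an empty term set; genes missing from
the network are treated as isolated nodes (all measures zero, disconnected).
Features are symmetric in the pair, so features(a, b) == features(b, a).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

#: node measures computed by default, in manifest order
DEFAULT_NODE_MEASURES = ("degree", "betweenness", "clustering", "closeness")

GRAPH_FEATURES = (
    "mean_degree",
    "mean_betweenness",
    "mean_clustering",
    "mean_closeness",
    "shortest_path",
    "connected",
)


class ConfigurationError(ValueError):
    """Raised for inconsistent feature configuration (e.g. duplicate namespaces)."""


@dataclass
class AnnotationCorpus:
    """One annotation namespace: a mapping gene id -> set of term ids."""

    namespace: str
    assignments: Mapping[str, frozenset[str]]

    def terms(self, gene: str) -> frozenset[str]:
        return self.assignments.get(gene.upper(), frozenset())


def dice_coefficient(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """Dice set-similarity ``2|A∩B| / (|A|+|B|)``; 0.0 when both sets are empty.

    Two empty term sets carry no evidence of shared function, so the empty/empty
    case is defined as 0 rather than 1.
    """
    a, b = set(set_a), set(set_b)
    denom = len(a) + len(b)
    if denom == 0:
        return 0.0
    return 2.0 * len(a & b) / denom


@dataclass(frozen=True)
class GraphPairFeatures:
    mean_degree: float
    mean_betweenness: float
    mean_clustering: float
    mean_closeness: float
    shortest_path: int
    connected: bool


class NodeMeasureCache:
    """Precomputed per-node measures for one graph.

    Betweenness and closeness are whole-graph computations; caching them makes
    featurising many pairs against the same network linear instead of
    quadratic in the number of queries.
    """

    def __init__(self, graph: nx.Graph):
        self.graph = graph
        self.n_nodes = graph.number_of_nodes()
        self.degree = dict(graph.degree())
        self.betweenness = nx.betweenness_centrality(graph, normalized=True)
        self.clustering = nx.clustering(graph)
        self.closeness = nx.closeness_centrality(graph)

    def measures(self, gene: str) -> tuple[float, float, float, float]:
        if gene not in self.graph:
            log.debug("gene %s absent from interaction graph; treated as isolated", gene)
            return (0.0, 0.0, 0.0, 0.0)
        return (
            float(self.degree[gene]),
            float(self.betweenness[gene]),
            float(self.clustering[gene]),
            float(self.closeness[gene]),
        )


def pair_graph_features(
    graph: nx.Graph,
    gene_a: str,
    gene_b: str,
    cache: NodeMeasureCache | None = None,
) -> GraphPairFeatures:
    """Mean node measures over the two endpoints plus geodesic distance.

    The disconnected sentinel for ``shortest_path`` is ``n_nodes + 1``: finite,
    and strictly larger than any realisable geodesic on the graph.
    """
    if gene_a == gene_b:
        raise ConfigurationError("pair endpoints must differ")
    if cache is None:
        cache = NodeMeasureCache(graph)
    ma, mb = cache.measures(gene_a), cache.measures(gene_b)
    sentinel = cache.n_nodes + 1
    if gene_a in graph and gene_b in graph:
        try:
            sp = int(nx.shortest_path_length(graph, gene_a, gene_b))
            connected = True
        except nx.NetworkXNoPath:
            sp, connected = sentinel, False
    else:
        sp, connected = sentinel, False
    return GraphPairFeatures(
        mean_degree=(ma[0] + mb[0]) / 2.0,
        mean_betweenness=(ma[1] + mb[1]) / 2.0,
        mean_clustering=(ma[2] + mb[2]) / 2.0,
        mean_closeness=(ma[3] + mb[3]) / 2.0,
        shortest_path=sp,
        connected=connected,
    )


def build_feature_vectors(
    pairs: Sequence[tuple[str, str]],
    corpora: Sequence[AnnotationCorpus],
    graph: nx.Graph,
) -> tuple[pd.DataFrame, list[str]]:
    """Assemble the feature table for a list of gene pairs.

    Returns ``(table, manifest)`` where the table carries ``gene_a``/``gene_b``
    columns followed by one ``dice_<namespace>`` column per corpus and the six
    graph-derived columns, and the manifest lists the feature columns in their
    fixed order.  The manifest is emitted even for an empty pair list so that
    downstream model/feature compatibility checks always have a reference.
    """
    namespaces = [c.namespace for c in corpora]
    if len(set(namespaces)) != len(namespaces):
        raise ConfigurationError(f"duplicate annotation namespaces: {namespaces}")
    manifest = [f"dice_{ns}" for ns in namespaces] + list(GRAPH_FEATURES)
    cache = NodeMeasureCache(graph)
    rows = []
    for a, b in pairs:
        a, b = a.upper(), b.upper()
        row: dict[str, object] = {"gene_a": min(a, b), "gene_b": max(a, b)}
        for corpus in corpora:
            row[f"dice_{corpus.namespace}"] = dice_coefficient(
                corpus.terms(a), corpus.terms(b)
            )
        gf = pair_graph_features(graph, a, b, cache=cache)
        row.update(
            mean_degree=gf.mean_degree,
            mean_betweenness=gf.mean_betweenness,
            mean_clustering=gf.mean_clustering,
            mean_closeness=gf.mean_closeness,
            shortest_path=gf.shortest_path,
            connected=int(gf.connected),
        )
        rows.append(row)
    table = pd.DataFrame(rows, columns=["gene_a", "gene_b"] + manifest)
    return table, manifest
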