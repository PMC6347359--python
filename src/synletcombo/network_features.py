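"""Per-node graph statistics and per-pair feature vectors.

The SL classifier describes a candidate gene pair by ten features computed
on a human gene-interaction network plus per-gene annotation profiles:

* five Dice coefficients, one per annotation namespace (pathway memberships
  from two pathway resources, a GO slim, disease terms, drug associations);
* the endpoint means of four node statistics (degree, betweenness,
  closeness, local clustering coefficient);
* the shortest-path hop count between the endpoints.

Conventions (fixed, since only relative values feed the classifier):
betweenness is the unnormalized Brandes count of dependent shortest-path
pairs with endpoints excluded; closeness is component-restricted and scaled
by component size (Wasserman-Faust), hence in [0, 1]; a disconnected pair's
shortest path is reported as ``n_nodes`` — one more than any real path, so
the feature stays finite and ordinal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .core import GenePair

#: Annotation namespaces, in frozen feature order.
NAMESPACES: tuple[str, ...] = (
    "pathway_kegg",
    "pathway_panther",
    "go_slim",
    "disease_mesh",
    "drug_assoc",
)

#: Node-statistic names, in frozen feature order.
STAT_NAMES: tuple[str, ...] = ("degree", "betweenness", "closeness", "clustering")

#: Frozen serialization order of the 10 pair features.
FEATURE_ORDER: tuple[str, ...] = tuple(
    [f"dice_{ns}" for ns in NAMESPACES]
    + [f"mean_{s}" for s in STAT_NAMES]
    + ["shortest_path"]
)

#: Version tag embedded in feature files and model artifacts so a trained
#: model is never silently applied to features in a different layout.
FEATURE_VERSION = "synletcombo-features-v1"


class InteractionNetwork:
    """Undirected gene-interaction network (no self-loops, no multi-edges)."""

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        nodes: Iterable[str] = (),
    ) -> None:
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop not allowed: {a!r}")
            g.add_edge(a, b)
        self._g = g

    @classmethod
    def from_graph(cls, graph: nx.Graph) -> "InteractionNetwork":
        net = cls()
        net._g = graph
        return net

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {(a, b) if a <= b else (b, a) for a, b in self._g.edges}

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, node: str) -> bool:
        return node in self._g


@dataclass(frozen=True)
class AnnotationProfile:
    """Per-gene term sets, one set per annotation namespace."""

    gene: str
    terms_by_namespace: Mapping[str, frozenset[str]]

    def terms(self, namespace: str) -> frozenset[str]:
        return self.terms_by_namespace.get(namespace, frozenset())


@dataclass(frozen=True)
class NodeStatistics:
    degree: int
    betweenness: float
    closeness: float
    clustering: float

    def as_dict(self) -> dict[str, float]:
        return {
            "degree": float(self.degree),
            "betweenness": self.betweenness,
            "closeness": self.closeness,
            "clustering": self.clustering,
        }


@dataclass(frozen=True)
class PairFeatureVector:
    """The 10-feature description of a gene pair, symmetric in endpoints."""

    dice: Mapping[str, float]
    mean_stats: Mapping[str, float]
    shortest_path: int
    feature_version: str = FEATURE_VERSION

    def as_array(self) -> np.ndarray:
        values = [self.dice[ns] for ns in NAMESPACES]
        values += [self.mean_stats[s] for s in STAT_NAMES]
        values.append(float(self.shortest_path))
        return np.asarray(values, dtype=float)

    @classmethod
    def from_array(
        cls, values: Sequence[float], feature_version: str = FEATURE_VERSION
    ) -> "PairFeatureVector":
        if len(values) != len(FEATURE_ORDER):
            raise ValueError(
                f"expected {len(FEATURE_ORDER)} features, got {len(values)}"
            )
        k = len(NAMESPACES)
        return cls(
            dice={ns: float(values[i]) for i, ns in enumerate(NAMESPACES)},
            mean_stats={
                s: float(values[k + i]) for i, s in enumerate(STAT_NAMES)
            },
            shortest_path=int(values[-1]),
            feature_version=feature_version,
        )


def dice_coefficient(set_a: frozenset | set, set_b: frozenset | set) -> float:
    """Dice set similarity 2|A∩B| / (|A|+|B|); 0 when both sets are empty.

    Two empty term sets carry no evidence of similarity, so their Dice is
    defined as 0 rather than 1.
    """
    total = len(set_a) + len(set_b)
    if total == 0:
        return 0.0
    return 2.0 * len(set(set_a) & set(set_b)) / total


def node_statistics(network: InteractionNetwork) -> dict[str, NodeStatistics]:
    """Degree, betweenness, closeness and clustering for every node."""
    g = network.graph
    if g.number_of_nodes() == 0:
        return {}
    betweenness = nx.betweenness_centrality(g, normalized=False)
    closeness = nx.closeness_centrality(g)  # Wasserman-Faust scaling
    clustering = nx.clustering(g)
    return {
        node: NodeStatistics(
            degree=g.degree(node),
            betweenness=float(betweenness[node]),
            closeness=float(closeness[node]),
            clustering=float(clustering[node]),
        )
        for node in g.nodes
    }


def disconnected_sentinel(network: InteractionNetwork) -> int:
    """Shortest-path value reported for disconnected pairs (= n_nodes)."""
    return network.n_nodes


def shortest_path_length(
    network: InteractionNetwork, a: str, b: str
) -> int:
    """Minimal hop count between two nodes; the sentinel if disconnected."""
    g = network.graph
    for node in (a, b):
        if node not in g:
            raise KeyError(f"unknown node: {node!r}")
    try:
        return int(nx.shortest_path_length(g, a, b))
    except nx.NetworkXNoPath:
        return disconnected_sentinel(network)


def eligible_nodes(
    profiles: Iterable[AnnotationProfile],
    required_namespaces: Sequence[str] = NAMESPACES,
) -> set[str]:
    """Genes with a non-empty term set in every required namespace.

    Mirrors the restriction of the modeling universe to fully annotated
    genes (data available from all annotation sources).
    """
    return {
        p.gene
        for p in profiles
        if all(len(p.terms(ns)) > 0 for ns in required_namespaces)
    }


def profiles_by_gene(
    profiles: Iterable[AnnotationProfile],
) -> dict[str, AnnotationProfile]:
    return {p.gene: p for p in profiles}


def build_pair_features(
    pair: GenePair,
    profiles: Mapping[str, AnnotationProfile],
    node_stats: Mapping[str, NodeStatistics],
    network: InteractionNetwork,
    shortest_path: int | None = None,
) -> PairFeatureVector:
    """Assemble the 10-feature vector for one gene pair.

    ``shortest_path`` may be supplied by a bulk caller that has already run
    the BFS (see :func:`build_feature_table`); otherwise it is computed here.
    Symmetric under endpoint swap by construction.
    """
    for gene in (pair.gene_a, pair.gene_b):
        if gene not in network:
            raise KeyError(f"gene not in network: {gene!r}")
        if gene not in profiles:
            raise KeyError(f"gene not in annotation profiles: {gene!r}")
    prof_a = profiles[pair.gene_a]
    prof_b = profiles[pair.gene_b]
    dice = {
        ns: dice_coefficient(prof_a.terms(ns), prof_b.terms(ns))
        for ns in NAMESPACES
    }
    stats_a = node_stats[pair.gene_a].as_dict()
    stats_b = node_stats[pair.gene_b].as_dict()
    mean_stats = {s: (stats_a[s] + stats_b[s]) / 2.0 for s in STAT_NAMES}
    if shortest_path is None:
        shortest_path = shortest_path_length(network, pair.gene_a, pair.gene_b)
    return PairFeatureVector(
        dice=dice, mean_stats=mean_stats, shortest_path=int(shortest_path)
    )


def build_feature_table(
    pairs: Sequence[GenePair],
    profiles: Mapping[str, AnnotationProfile],
    node_stats: Mapping[str, NodeStatistics],
    network: InteractionNetwork,
) -> list[tuple[GenePair, PairFeatureVector]]:
    """Feature vectors for many pairs, caching one BFS per distinct source."""
    g = network.graph
    sentinel = disconnected_sentinel(network)
    bfs_cache: dict[str, dict[str, int]] = {}
    out = []
    for pair in pairs:
        src = pair.gene_a
        if src not in bfs_cache:
            if src not in g:
                raise KeyError(f"gene not in network: {src!r}")
            bfs_cache[src] = dict(nx.single_source_shortest_path_length(g, src))
        sp = bfs_cache[src].get(pair.gene_b, sentinel)
        out.append(
            (
                pair,
                build_pair_features(
                    pair, profiles, node_stats, network, shortest_path=sp
                ),
            )
        )
    return out
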