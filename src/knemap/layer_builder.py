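"""Build per-layer weighted gene-gene similarity networks from prior knowledge.

Two kinds of raw prior knowledge are turned into layers:

* gene-gene evidence edges (e.g. protein-protein interactions), where the
  edge weight is the number of distinct data sources supporting the edge;
* gene-entity association sets (e.g. gene-disease, gene-pathway), where two
  genes are connected iff they share at least one entity and the weight is
  the number of shared entities.

Layer weights are subsequently scaled into (0, 1] by dividing by the layer
maximum, so that a value close to 1 means strong similarity and relative
weight ratios are preserved.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import networkx as nx

__all__ = [
    "EvidenceEdge",
    "AssociationTable",
    "LayerNetwork",
    "build_layer_from_edges",
    "build_layer_from_associations",
    "scale_layer_weights",
]

Pair = tuple[str, str]


def _check_gene(symbol: str) -> str:
    if not isinstance(symbol, str) or not symbol or any(c.isspace() for c in symbol):
        raise ValueError(f"invalid gene identifier: {symbol!r}")
    return symbol


def pair_key(a: str, b: str) -> Pair:
    """Canonical unordered-pair key (lexicographically sorted)."""
    return (a, b) if a <= b else (b, a)


class EvidenceEdge(NamedTuple):
    gene_a: str
    gene_b: str
    source: str


@dataclass(frozen=True)
class AssociationTable:
    """Gene-entity association pairs in one namespace (disease, pathway, ...)."""

    namespace: str
    pairs: frozenset[tuple[str, str]]  # (gene, entity_id)

    def entities_by_gene(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = defaultdict(set)
        for gene, entity in self.pairs:
            out[gene].add(entity)
        return dict(out)


@dataclass
class LayerNetwork:
    """One named, weighted, undirected gene-gene similarity graph.

    Edges are stored on canonical unordered pairs, so the graph is symmetric
    by construction and self-loops cannot be represented.
    """

    name: str
    nodes: set[str] = field(default_factory=set)
    edges: dict[Pair, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (a, b), w in self.edges.items():
            if a == b:
                raise ValueError(f"self-loop on gene {a!r}")
            if (a, b) != pair_key(a, b):
                raise ValueError(f"edge key {(a, b)} is not in canonical order")
            if w <= 0:
                raise ValueError(f"non-positive weight {w} on edge {(a, b)}")
        self.nodes = set(self.nodes)
        for a, b in self.edges:
            self.nodes.add(a)
            self.nodes.add(b)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def weight(self, a: str, b: str) -> float:
        """Weight of the unordered pair {a, b}; 0.0 if the edge is absent."""
        return self.edges.get(pair_key(a, b), 0.0)

    def max_weight(self) -> float:
        if not self.edges:
            raise ValueError(f"layer {self.name!r} has no edges")
        return max(self.edges.values())

    def binary_edges(self) -> frozenset[Pair]:
        return frozenset(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(name=self.name)
        g.add_nodes_from(sorted(self.nodes))
        g.add_weighted_edges_from((a, b, w) for (a, b), w in self.edges.items())
        return g


def build_layer_from_edges(edges: Iterable[tuple[str, str, str]], name: str) -> LayerNetwork:
    """Build a layer from gene-gene evidence edges.

    The weight of pair {a, b} is the number of *distinct* source labels
    supporting it; duplicated (a, b, source) triples count once.
    """
    sources: dict[Pair, set[str]] = defaultdict(set)
    nodes: set[str] = set()
    n = 0
    for gene_a, gene_b, source in edges:
        n += 1
        _check_gene(gene_a)
        _check_gene(gene_b)
        if gene_a == gene_b:
            raise ValueError(f"self-loop edge on gene {gene_a!r} (source {source!r})")
        sources[pair_key(gene_a, gene_b)].add(source)
        nodes.add(gene_a)
        nodes.add(gene_b)
    if n == 0:
        raise ValueError("no evidence edges provided")
    weights = {p: float(len(s)) for p, s in sources.items()}
    return LayerNetwork(name=name, nodes=nodes, edges=weights)


def build_layer_from_associations(assoc: AssociationTable, name: str) -> LayerNetwork:
    """Convert gene-entity associations into a gene-gene similarity layer.

    Pair {a, b} is connected iff the genes share >= 1 entity; the weight is
    the shared-entity count. Genes that share nothing with anyone stay in the
    node set as isolated nodes so layers over the same universe remain
    comparable.
    """
    if not assoc.pairs:
        raise ValueError("empty association table")
    by_entity: dict[str, set[str]] = defaultdict(set)
    nodes: set[str] = set()
    for gene, entity in assoc.pairs:
        _check_gene(gene)
        by_entity[entity].add(gene)
        nodes.add(gene)
    shared: dict[Pair, int] = defaultdict(int)
    for genes in by_entity.values():
        members = sorted(genes)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                shared[(a, b)] += 1
    weights = {p: float(c) for p, c in shared.items()}
    return LayerNetwork(name=name, nodes=nodes, edges=weights)


def scale_layer_weights(layer: LayerNetwork) -> LayerNetwork:
    """Scale edge weights into (0, 1] by dividing by the layer maximum.

    Division by the maximum (rather than min-max) keeps weight ratios and
    never maps a real edge to 0, which would be indistinguishable from an
    absent edge. Idempotent, and preserves node and edge sets.
    """
    m = layer.max_weight()
    return LayerNetwork(
        name=layer.name,
        nodes=set(layer.nodes),
        edges={p: w / m for p, w in layer.edges.items()},
    )
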