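"""Fuse prior-knowledge layers into one weighted gene similarity network.

The fusion is hierarchical and data driven. First the layers are compared on
their *binary* edge sets (an edge is present or not; weights are ignored at
this stage) with a combined distance: the sum of the Jaccard distance, the
simple-matching-coefficient (SMC) distance over the union-of-edges universe,
and a shared-edge-fraction distance. Ward hierarchical clustering on that
matrix groups layers that span similar regions of the gene space. Layers
within a cluster are merged first — each layer's weights rescaled to a common
median and then summed edge-wise — and the resulting cluster networks are
merged the same way in a second step. The final weights are scaled into
(0, 1] by dividing by the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .layer_builder import LayerNetwork, Pair

__all__ = [
    "LayerDistanceMatrix",
    "LayerClustering",
    "PriorNetwork",
    "binary_layer_distance",
    "cluster_layers",
    "merge_networks",
    "fuse_hierarchical",
    "network_density",
]


def network_density(n_nodes: int, n_edges: int) -> float:
    """Density of a simple undirected graph: n_edges / (n_nodes choose 2)."""
    if n_nodes < 2:
        raise ValueError("density needs at least 2 nodes")
    return n_edges / (n_nodes * (n_nodes - 1) / 2)


@dataclass
class LayerDistanceMatrix:
    """Pairwise binary-edge distance between layers.

    ``D`` is the equally weighted sum of the three components, min-max scaled
    over its off-diagonal entries into [0, 1] with a zero diagonal. The
    unscaled components are kept for audit.
    """

    layer_names: list[str]
    D: np.ndarray
    components: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)


@dataclass
class LayerClustering:
    assignment: dict[str, int]
    k: int


@dataclass
class PriorNetwork:
    """The fused gene similarity network, weights in (0, 1]."""

    nodes: set[str]
    edges: dict[Pair, float]
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def density(self) -> float:
        return network_density(self.n_nodes, self.n_edges)

    def weight(self, a: str, b: str) -> float:
        from .layer_builder import pair_key

        return self.edges.get(pair_key(a, b), 0.0)

    def as_layer(self, name: str = "prior") -> LayerNetwork:
        return LayerNetwork(name=name, nodes=set(self.nodes), edges=dict(self.edges))


_SHARED_DENOMS = ("min", "mean", "union")


def binary_layer_distance(
    layers: Sequence[LayerNetwork],
    shared_fraction_denominator: str = "min",
) -> LayerDistanceMatrix:
    """Combined binary-edge distance between all layer pairs.

    For layers i, j with binary edge sets E_i, E_j and universe U = union of
    edges over *all* layers passed in:

    * jaccard  = 1 - |E_i n E_j| / |E_i u E_j|
    * smc      = 1 - matches / |U|, a match being an edge of U present in
      both or absent from both (the universe is the observed edge union, not
      all gene pairs, so the score is not swamped by shared absences)
    * shared   = 1 - |E_i n E_j| / denom(E_i, E_j); with the default ``min``
      denominator this measures containment of the smaller layer

    The three components are summed with equal weight and the result is
    min-max scaled over the off-diagonal entries into [0, 1]. Layers are
    ordered lexicographically by name so downstream Ward clustering is
    deterministic.
    """
    if len(layers) < 2:
        raise ValueError("need at least 2 layers")
    if shared_fraction_denominator not in _SHARED_DENOMS:
        raise ValueError(f"shared_fraction_denominator must be one of {_SHARED_DENOMS}")
    for layer in layers:
        if layer.n_edges == 0:
            raise ValueError(f"layer {layer.name!r} has no edges")
    ordered = sorted(layers, key=lambda l: l.name)
    names = [l.name for l in ordered]
    if len(set(names)) != len(names):
        raise ValueError("layer names must be unique")
    sets = [l.binary_edges() for l in ordered]
    universe = frozenset().union(*sets)
    n = len(ordered)
    jac = np.zeros((n, n))
    smc = np.zeros((n, n))
    sha = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[i] & sets[j])
            union = len(sets[i] | sets[j])
            jac[i, j] = jac[j, i] = 1.0 - inter / union
            matches = inter + len(universe) - union  # both-present + both-absent over U
            smc[i, j] = smc[j, i] = 1.0 - matches / len(universe)
            if shared_fraction_denominator == "min":
                denom = min(len(sets[i]), len(sets[j]))
            elif shared_fraction_denominator == "mean":
                denom = (len(sets[i]) + len(sets[j])) / 2
            else:
                denom = union
            sha[i, j] = sha[j, i] = 1.0 - inter / denom
    raw = jac + smc + sha
    off = ~np.eye(n, dtype=bool)
    lo, hi = raw[off].min(), raw[off].max()
    D = np.zeros_like(raw)
    if hi > lo:
        D[off] = (raw[off] - lo) / (hi - lo)
    return LayerDistanceMatrix(
        layer_names=names,
        D=D,
        components={"jaccard": jac, "smc": smc, "shared_fraction": sha, "raw_sum": raw},
        meta={
            "smc_universe_size": len(universe),
            "shared_fraction_denominator": shared_fraction_denominator,
        },
    )


def cluster_layers(dist: LayerDistanceMatrix, k: int) -> LayerClustering:
    """Ward-linkage agglomerative clustering of the layers, cut at k clusters."""
    n = len(dist.layer_names)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    if k == n:
        labels = np.arange(n) + 1
    else:
        Z = linkage(squareform(dist.D, checks=False), method="ward")
        labels = fcluster(Z, t=k, criterion="maxclust")
    # relabel 0-based in order of first appearance for determinism
    remap: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for name, lab in zip(dist.layer_names, labels):
        if lab not in remap:
            remap[lab] = len(remap)
        assignment[name] = remap[lab]
    return LayerClustering(assignment=assignment, k=len(remap))


def merge_networks(layers: Sequence[LayerNetwork], target_median: float = 0.5) -> LayerNetwork:
    """Median-aligned additive merge of weighted layers.

    Each layer's weights are multiplied by ``target_median / median(weights)``
    so all layers contribute on the same scale, then weights are summed over
    the union of edges (an absent edge contributes 0). The result is *not*
    range-scaled; callers rescale after merging.
    """
    if not layers:
        raise ValueError("need at least 1 layer")
    if target_median <= 0:
        raise ValueError("target_median must be positive")
    merged: dict[Pair, float] = {}
    nodes: set[str] = set()
    for layer in layers:
        if layer.n_edges == 0:
            raise ValueError(f"layer {layer.name!r} has no edges")
        factor = target_median / median(layer.edges.values())
        nodes |= layer.nodes
        for p, w in layer.edges.items():
            merged[p] = merged.get(p, 0.0) + w * factor
    name = "+".join(sorted(l.name for l in layers))
    return LayerNetwork(name=name, nodes=nodes, edges=merged)


def fuse_hierarchical(
    layers: Sequence[LayerNetwork],
    clustering: LayerClustering,
    target_median: float = 0.5,
) -> PriorNetwork:
    """Two-stage merge: within layer clusters first, then across them.

    Stage 1 merges the layers of each cluster (median-aligned sum) and scales
    each cluster network into (0, 1] by its maximum. Stage 2 merges the
    cluster networks the same way and scales the final weights by the global
    maximum, so the fused network again has weights in (0, 1].
    """
    from .layer_builder import scale_layer_weights

    by_name = {l.name: l for l in layers}
    missing = set(by_name) - set(clustering.assignment)
    if missing:
        raise ValueError(f"clustering does not cover layers: {sorted(missing)}")
    groups: dict[int, list[LayerNetwork]] = {}
    for name in sorted(by_name):
        groups.setdefault(clustering.assignment[name], []).append(by_name[name])

    cluster_nets = []
    merge_tree = []
    for cid in sorted(groups):
        merged = scale_layer_weights(merge_networks(groups[cid], target_median))
        merged.name = f"cluster{cid}"
        cluster_nets.append(merged)
        merge_tree.append({"step": 1, "cluster": cid, "layers": sorted(l.name for l in groups[cid])})
    final = merge_networks(cluster_nets, target_median)
    final = scale_layer_weights(final)
    merge_tree.append({"step": 2, "merged": [n.name for n in cluster_nets]})
    return PriorNetwork(
        nodes=final.nodes,
        edges=final.edges,
        provenance={
            "merge_tree": merge_tree,
            "target_median": target_median,
            "final_scaling": "division_by_max",
            "k": clustering.k,
        },
    )
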