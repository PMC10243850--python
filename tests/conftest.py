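import numpy as np
import pytest

from knemap import (
    FingerprintContext,
    SyntheticConfig,
    binary_layer_distance,
    cluster_layers,
    detect_communities,
    differential_profile,
    fuse_hierarchical,
    generate_exposures,
    generate_layers,
)
from knemap.layer_builder import scale_layer_weights


@pytest.fixture(scope="session")
def cfg():
    """Small default study conditions shared across pipeline tests."""
    return SyntheticConfig(seed=11, n_systems=2, n_exposures=12)


@pytest.fixture(scope="session")
def pipeline(cfg):
    """Layers -> fused prior -> partition, computed once per session."""
    layers, blocks = generate_layers(cfg)
    scaled = [scale_layer_weights(l) for l in layers]
    dist = binary_layer_distance(scaled)
    clustering = cluster_layers(dist, 3)
    prior = fuse_hierarchical(scaled, clustering)
    partition = detect_communities(prior)
    return {
        "layers": scaled,
        "blocks": blocks,
        "dist": dist,
        "clustering": clustering,
        "prior": prior,
        "partition": partition,
    }


@pytest.fixture(scope="session")
def exposures(cfg, pipeline):
    return generate_exposures(cfg, pipeline["blocks"])


@pytest.fixture(scope="session")
def profiles_by_system(exposures):
    expr = exposures.expression
    return {
        s: [differential_profile(expr, s, e) for e in expr.exposures(s)]
        for s in expr.systems()
    }


@pytest.fixture(scope="session")
def ctx(cfg, pipeline):
    return FingerprintContext(
        partition=pipeline["partition"],
        network_genes=set(pipeline["partition"].assignment),
        universe=cfg.gene_ids(),
        gsea_n_perm=150,
    )
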