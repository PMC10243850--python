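"""Seeded generators for every input the pipeline consumes.

The generators plant recoverable structure at desk scale:

* layered gene-gene networks whose genes fall into blocks (planted
  modules): intra-block edges are sampled with high probability and
  inter-block edges with low probability in every layer, with integer
  weights 1-3 emulating evidence counts;
* replicate expression matrices and differential-expression profiles for
  compound exposures on several biological systems, where planted compound
  groups share a signature set of blocks whose genes are shifted by a fixed
  effect size (with per-system multipliers, so groups cohere within a
  system but not across systems);
* compound annotations: class labels equal to the planted groups and
  structure strings whose edit distance is smaller within groups (shared
  group prefix plus a random suffix).

Everything is deterministic per seed, and the planted truth (blocks,
groups, signatures) is always returned alongside the data so recovery can
be scored.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .fingerprints import DEProfile, ExpressionMatrix, P_FLOOR
from .layer_builder import LayerNetwork, pair_key

__all__ = [
    "SyntheticConfig",
    "SyntheticExposures",
    "generate_layers",
    "generate_exposures",
    "generate_annotations",
]


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic fixtures.

    Defaults are toy scale — 300 genes over 20 blocks, 6 knowledge layers,
    30 exposures in 3 planted groups on 2 systems — chosen so the full
    pipeline runs in minutes while keeping the qualitative regime of the
    real application (a dense fused network partitioned into many small
    communities, compound groups separable within a system). The default
    effect size of 4 with unit noise gives a signal-to-noise ratio of 4.
    """

    seed: int = 0
    # prior-knowledge layers
    n_genes: int = 300
    n_layers: int = 6
    n_blocks: int = 20
    intra_block_edge_prob: float = 0.6
    inter_block_edge_prob: float = 0.01
    # exposures
    n_systems: int = 2
    n_exposures: int = 30
    n_groups: int = 3
    blocks_per_group: int = 3
    effect_size: float = 4.0
    replicate_count: int = 3
    noise_sd: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    # annotations
    n_classes: int | None = None  # defaults to n_groups
    label_noise: float = 0.0
    alphabet: str = "CNOPS()=#123456"
    prefix_len: int = 6
    suffix_len: int = 10

    def __post_init__(self) -> None:
        for p in (self.intra_block_edge_prob, self.inter_block_edge_prob, self.label_noise):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise ValueError("effect_size and noise_sd must be >= 0")
        if self.replicate_count < 2:
            raise ValueError("replicate_count must be >= 2")
        for n in (self.n_genes, self.n_layers, self.n_blocks, self.n_systems,
                  self.n_exposures, self.n_groups, self.blocks_per_group):
            if n < 1:
                raise ValueError("all sizes must be >= 1")

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def exposure_ids(self) -> list[str]:
        width = len(str(self.n_exposures))
        return [f"D{i:0{width}d}" for i in range(1, self.n_exposures + 1)]

    def system_ids(self) -> list[str]:
        return [f"S{i}" for i in range(1, self.n_systems + 1)]


def _assign_blocks(cfg: SyntheticConfig, rng: np.random.Generator) -> dict[str, int]:
    genes = cfg.gene_ids()
    perm = rng.permutation(len(genes))
    return {genes[int(i)]: int(b % cfg.n_blocks) for b, i in enumerate(perm)}


def generate_layers(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[list[LayerNetwork], dict[str, int]]:
    """Sample knowledge layers sharing planted gene blocks.

    Every layer draws intra-block pairs with ``intra_block_edge_prob`` and
    inter-block pairs with ``inter_block_edge_prob``; integer weights 1-3
    emulate per-source evidence counts. Layers share the block structure but
    differ in realized edges. An (unlikely) empty layer is resampled up to
    10 times before erroring.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    blocks = _assign_blocks(cfg, rng)
    genes = cfg.gene_ids()
    pairs = [pair_key(a, b) for a, b in itertools.combinations(genes, 2)]
    intra = np.array([blocks[a] == blocks[b] for a, b in pairs])
    probs = np.where(intra, cfg.intra_block_edge_prob, cfg.inter_block_edge_prob)
    layers: list[LayerNetwork] = []
    for li in range(cfg.n_layers):
        for _attempt in range(10):
            mask = rng.random(len(pairs)) < probs
            if mask.any():
                break
        else:
            raise ValueError("could not sample a non-empty layer in 10 attempts")
        idx = np.nonzero(mask)[0]
        weights = rng.integers(1, 4, size=len(idx))
        edges = {pairs[int(i)]: float(w) for i, w in zip(idx, weights)}
        layers.append(LayerNetwork(name=f"layer{li}", nodes=set(genes), edges=edges))
    return layers, blocks


@dataclass
class SyntheticExposures:
    expression: ExpressionMatrix
    true_profiles: dict[tuple[str, str], DEProfile]  # (system, exposure)
    group_labels: dict[str, int]  # exposure -> planted group
    signatures: dict[int, set[str]]  # group -> signature genes
    signature_signs: dict[int, dict[str, float]]


def generate_exposures(
    cfg: SyntheticConfig,
    blocks: dict[str, int],
    rng: np.random.Generator | None = None,
) -> SyntheticExposures:
    """Simulate replicate expression data with planted compound groups.

    Each group owns a signature of ``blocks_per_group`` blocks (round-robin
    over the available blocks). Treated samples shift the signature genes by
    ``effect_size`` with a fixed per-gene sign, modulated by a per-system
    multiplier drawn in U(0.5, 1.5) with occasional sign flips — groups
    therefore cohere within a system but their cross-system patterns
    differ. All entries carry additive N(0, noise_sd) measurement noise on
    an additive log-like scale, so the Welch stand-in's logFC estimates the
    planted shift. Exact noise-free profiles are emitted alongside: logFC is
    the planted shift, and the p-value is the expected two-sided normal
    tail of that shift at the configured replicate count and noise level.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    genes = cfg.gene_ids()
    systems = cfg.system_ids()
    exposures = cfg.exposure_ids()
    group_labels = {e: i % cfg.n_groups for i, e in enumerate(exposures)}

    block_ids = sorted(set(blocks.values()))
    signatures: dict[int, set[str]] = {}
    signature_signs: dict[int, dict[str, float]] = {}
    for g in range(cfg.n_groups):
        sig_blocks = {block_ids[(g * cfg.blocks_per_group + j) % len(block_ids)]
                      for j in range(cfg.blocks_per_group)}
        sig = {gene for gene, b in blocks.items() if b in sig_blocks}
        if len(sig) >= len(genes):
            raise ValueError("signature covers the whole gene universe")
        signatures[g] = sig
        signature_signs[g] = {
            gene: float(s) for gene, s in zip(sorted(sig), rng.choice([-1.0, 1.0], size=len(sig)))
        }

    # per-system modulation of each group's signature
    multipliers: dict[tuple[str, int], dict[str, float]] = {}
    for s in systems:
        for g in range(cfg.n_groups):
            genes_g = sorted(signatures[g])
            mags = rng.uniform(0.5, 1.5, size=len(genes_g))
            flips = np.where(rng.random(len(genes_g)) < 0.3, -1.0, 1.0)
            multipliers[(s, g)] = {
                gene: float(m * f) for gene, m, f in zip(genes_g, mags, flips)
            }

    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(genes))
    system_offset = {s: rng.normal(0.0, 0.25, size=len(genes)) for s in systems}
    # mild exposure-specific magnitude jitter so group members are not clones
    jitter = {e: float(rng.uniform(0.8, 1.2)) for e in exposures}

    rows = []
    info_rows = []
    gene_index = {g: i for i, g in enumerate(genes)}
    true_profiles: dict[tuple[str, str], DEProfile] = {}
    noise_scale = cfg.noise_sd * np.sqrt(2.0 / cfg.replicate_count)
    for s in systems:
        base = mu + system_offset[s]
        for r in range(cfg.replicate_count):
            rows.append(base + rng.normal(0.0, cfg.noise_sd, size=len(genes)))
            info_rows.append((f"{s}_ctrl_{r}", s, "", "control"))
        for e in exposures:
            g = group_labels[e]
            shift = np.zeros(len(genes))
            for gene in signatures[g]:
                shift[gene_index[gene]] = (
                    signature_signs[g][gene]
                    * cfg.effect_size
                    * multipliers[(s, g)][gene]
                    * jitter[e]
                )
            for r in range(cfg.replicate_count):
                rows.append(base + shift + rng.normal(0.0, cfg.noise_sd, size=len(genes)))
                info_rows.append((f"{s}_{e}_{r}", s, e, "treated"))
            if cfg.noise_sd > 0:
                z = np.abs(shift) / noise_scale
                p = np.clip(2.0 * norm.sf(z), P_FLOOR, 1.0)
            else:
                p = np.where(shift != 0, P_FLOOR, 1.0)
            table = pd.DataFrame({"logFC": shift, "pvalue": p}, index=genes)
            table.index.name = "gene"
            true_profiles[(s, e)] = DEProfile(exposure_id=e, system_id=s, table=table)

    sample_ids = [r[0] for r in info_rows]
    values = pd.DataFrame(np.vstack(rows), index=sample_ids, columns=genes)
    sample_info = pd.DataFrame(
        [r[1:] for r in info_rows], index=sample_ids, columns=["system", "exposure", "group"]
    )
    expr = ExpressionMatrix(values=values, sample_info=sample_info)
    return SyntheticExposures(
        expression=expr,
        true_profiles=true_profiles,
        group_labels=group_labels,
        signatures=signatures,
        signature_signs=signature_signs,
    )


def generate_annotations(
    cfg: SyntheticConfig,
    group_labels: dict[str, int],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Class labels and structure strings reflecting the planted groups.

    The class label equals the planted group (optionally corrupted with
    ``label_noise`` fraction of random relabels); structure strings share a
    group-specific prefix followed by a random suffix, so within-group edit
    distances are smaller in expectation. Returns a DataFrame indexed by
    exposure with columns ``class_label`` and ``structure``.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    n_classes = cfg.n_classes or cfg.n_groups
    alphabet = np.array(list(cfg.alphabet))

    def rand_string(length: int) -> str:
        return "".join(rng.choice(alphabet, size=length))

    prefixes = {g: rand_string(cfg.prefix_len) for g in range(n_classes)}
    records = []
    for e in sorted(group_labels):
        g = group_labels[e] % n_classes
        label = g
        if cfg.label_noise > 0 and rng.random() < cfg.label_noise:
            label = int(rng.integers(n_classes))
        structure = prefixes[g] + rand_string(cfg.suffix_len)
        records.append((e, f"C{label}", structure))
    df = pd.DataFrame(records, columns=["exposure", "class_label", "structure"])
    return df.set_index("exposure")
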