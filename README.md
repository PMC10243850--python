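# knemap

Knowledge-driven network mapping of transcriptomic exposure profiles.

## The problem

Transcriptomic profiles of chemical exposures (drugs, nanomaterials) are
routinely compared to infer shared mechanisms of action, but gene-level
comparisons — correlating fold changes or intersecting deregulated gene
sets — are fragile: they inherit technical and biological variance and
ignore the relationships between genes. `knemap` replaces the
individual-gene view with a *similar-gene* view. Multiple layers of prior
knowledge (protein–protein interactions, pathway co-membership, shared
disease associations, homology, …) are fused into one weighted gene–gene
similarity network, the network is partitioned into many small communities,
and each exposure is represented by how its most deregulated genes
distribute over those communities. Exposures measured on different
platforms or datasets become directly comparable as long as they are mapped
onto the same prior network.

The package is for computational toxicologists and systems biologists who
want to fingerprint, cluster and match exposures across biological systems,
and to benchmark such fingerprints against standard baselines.

## The method

Per gene and exposure, deregulation is scored by

    FCP = logFC · (−log₁₀ p)

After restricting to genes in the prior network, the 100 most positive and
100 most negative FCP genes are selected. The **community-fraction
fingerprint** of the exposure is the vector

    f_c = |selection ∩ community_c| / |selection|,   c = 1 … #communities

Three baselines are built from the same data: **BDG** (binary vector of the
selection over the measured genes), **FC** (raw FCP values on a common gene
ordering), and **GSEA** (preranked enrichment p-values of the selection
against every other exposure's FCP-ranked list in the same system, weighted
Kolmogorov–Smirnov with gene-label permutations).

The prior network itself is fused hierarchically: layers are compared on
their binary edge sets (Jaccard + simple matching coefficient + shared-edge
fraction, equally weighted), Ward-clustered, merged within clusters by
median-aligned summation, then merged across clusters, with weights scaled
into (0, 1]. Communities come from agglomerative clustering on the
distances 1 − weight at threshold 0.5. See `docs/methods.md` for every
modelling choice.

## Worked example

Everything below runs from synthetic data generated by the package itself;
the planted structure (gene blocks, compound groups) makes recovery
checkable.

```
knemap simulate --seed 1 --out demo/
knemap fuse --layers-dir demo/layers --k 3 --out demo/prior.tsv
knemap communities --prior demo/prior.tsv --threshold 0.5 --out demo/partition.tsv
knemap fingerprint --profiles-dir demo/profiles --partition demo/partition.tsv \
    --method knemap --out-dir demo/vectors
```

which prints

```
wrote synthetic dataset to demo
prior network: 300 nodes, 4537 edges, density 0.101
20 communities, mean size 15.0
wrote knemap vectors to demo/vectors
```

The fused prior network covers all 300 simulated genes; its 20 communities
of mean size 15.0 recover the 20 planted gene blocks. Each row of
`demo/vectors/S1.knemap.tsv` is one exposure's fingerprint over the 20
communities and sums to 1. The same Python API is available as
`knemap.build_layer_from_edges`, `knemap.fuse_hierarchical`,
`knemap.detect_communities`, `knemap.select_deregulated`,
`knemap.knemap_vector`, etc., and the benchmark experiments live in
`knemap.comparison_benchmarks` (`knemap benchmark --task …` on the command
line).

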