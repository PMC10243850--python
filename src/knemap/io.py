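"""Readers and writers for the plain-text dialects used by the pipeline.

* evidence edges: 3-column TSV ``gene_a  gene_b  source`` (header required)
* associations: GMT — one line per entity: ``entity_id  description  gene1  gene2 ...``
* layers / prior network: weighted edge-list TSV ``gene_a  gene_b  weight``
  plus a JSON sidecar with metadata (name, counts, provenance)
* community partition: 2-column TSV ``gene  community_id`` + JSON stats
* differential-expression profiles: TSV ``gene  logFC  pvalue``, one file
  per exposure x system named ``<system>__<exposure>.tsv``
* feature vectors: TSV matrices, rows = exposures
* annotations: TSV ``exposure  class_label  structure_string``
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .community_detection import CommunityPartition, partition_stats
from .fingerprints import DEProfile, ExpressionMatrix
from .layer_builder import AssociationTable, EvidenceEdge, LayerNetwork, pair_key
from .network_fusion import PriorNetwork

__all__ = [
    "read_evidence_edges",
    "read_gmt",
    "write_layer",
    "read_layer",
    "write_prior_network",
    "read_prior_network",
    "write_partition",
    "read_partition",
    "write_profile",
    "read_profile",
    "read_profiles_dir",
    "write_vectors",
    "read_vectors",
    "write_annotations",
    "read_annotations",
    "write_expression",
    "read_expression",
]


def read_evidence_edges(path: str | Path) -> list[EvidenceEdge]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = ["gene_a", "gene_b", "source"]
    if list(df.columns[:3]) != need:
        raise ValueError(f"evidence TSV must have header columns {need}")
    return [EvidenceEdge(r.gene_a, r.gene_b, r.source) for r in df.itertuples(index=False)]


def read_gmt(path: str | Path, namespace: str = "") -> AssociationTable:
    pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line needs entity, description, >=1 gene: {line!r}")
            entity = fields[0]
            for gene in fields[2:]:
                if gene:
                    pairs.add((gene, entity))
    return AssociationTable(namespace=namespace or Path(path).stem, pairs=frozenset(pairs))


def _write_edges_tsv(path: Path, edges: dict, nodes: set[str]) -> None:
    rows = sorted(edges.items())
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for (a, b), w in rows:
            fh.write(f"{a}\t{b}\t{w:.12g}\n")
    isolated = sorted(nodes - {g for p in edges for g in p})
    if isolated:
        iso_path = path.with_suffix(".isolated.txt")
        iso_path.write_text("\n".join(isolated) + "\n")


def _read_edges_tsv(path: Path) -> tuple[dict, set[str]]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str, "weight": float})
    edges = {
        pair_key(r.gene_a, r.gene_b): float(r.weight) for r in df.itertuples(index=False)
    }
    nodes = {g for p in edges for g in p}
    iso_path = path.with_suffix(".isolated.txt")
    if iso_path.exists():
        nodes |= {l for l in iso_path.read_text().splitlines() if l}
    return edges, nodes


def write_layer(layer: LayerNetwork, path: str | Path) -> None:
    path = Path(path)
    _write_edges_tsv(path, layer.edges, layer.nodes)
    meta = {"name": layer.name, "n_nodes": layer.n_nodes, "n_edges": layer.n_edges}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")


def read_layer(path: str | Path) -> LayerNetwork:
    path = Path(path)
    edges, nodes = _read_edges_tsv(path)
    meta_path = path.with_suffix(".json")
    name = json.loads(meta_path.read_text())["name"] if meta_path.exists() else path.stem
    return LayerNetwork(name=name, nodes=nodes, edges=edges)


def write_prior_network(prior: PriorNetwork, path: str | Path) -> None:
    path = Path(path)
    _write_edges_tsv(path, prior.edges, prior.nodes)
    meta = {
        "n_nodes": prior.n_nodes,
        "n_edges": prior.n_edges,
        "provenance": prior.provenance,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")


def read_prior_network(path: str | Path) -> PriorNetwork:
    path = Path(path)
    edges, nodes = _read_edges_tsv(path)
    meta_path = path.with_suffix(".json")
    provenance = (
        json.loads(meta_path.read_text()).get("provenance", {}) if meta_path.exists() else {}
    )
    return PriorNetwork(nodes=nodes, edges=edges, provenance=provenance)


def write_partition(partition: CommunityPartition, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene\tcommunity_id\n")
        for gene in sorted(partition.assignment):
            fh.write(f"{gene}\t{partition.assignment[gene]}\n")
    stats = partition_stats(partition)
    stats["size_histogram"] = {str(k): v for k, v in stats["size_histogram"].items()}
    path.with_suffix(".json").write_text(json.dumps(stats, indent=2) + "\n")


def read_partition(path: str | Path) -> CommunityPartition:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "community_id": int})
    return CommunityPartition(
        assignment={r.gene: int(r.community_id) for r in df.itertuples(index=False)}
    )


def profile_filename(profile: DEProfile) -> str:
    return f"{profile.system_id}__{profile.exposure_id}.tsv"


def write_profile(profile: DEProfile, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / profile_filename(profile)
    out = profile.table.reset_index()
    out.columns = ["gene", "logFC", "pvalue"]
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return path


def read_profile(path: str | Path) -> DEProfile:
    path = Path(path)
    system, _, exposure = path.stem.partition("__")
    if not exposure:
        raise ValueError(f"profile filename must be <system>__<exposure>.tsv: {path.name}")
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    table = df.set_index("gene")[["logFC", "pvalue"]].astype(float)
    return DEProfile(exposure_id=exposure, system_id=system, table=table)


def read_profiles_dir(directory: str | Path) -> dict[str, list[DEProfile]]:
    """All profiles in a directory, grouped by system id."""
    out: dict[str, list[DEProfile]] = {}
    for path in sorted(Path(directory).glob("*.tsv")):
        p = read_profile(path)
        out.setdefault(p.system_id, []).append(p)
    if not out:
        raise ValueError(f"no profile TSVs in {directory}")
    return out


def write_vectors(
    vectors: dict[str, np.ndarray], path: str | Path, columns: list[str] | None = None
) -> None:
    """Feature vectors as a TSV matrix, one row per exposure."""
    ids = sorted(vectors)
    mat = np.vstack([vectors[e] for e in ids])
    cols = columns if columns is not None else [str(i) for i in range(mat.shape[1])]
    df = pd.DataFrame(mat, index=pd.Index(ids, name="exposure"), columns=cols)
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_vectors(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col="exposure")
    return {str(e): df.loc[e].to_numpy(dtype=float) for e in df.index}


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    annotations.to_csv(path, sep="\t")


def read_annotations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str).set_index("exposure")


def write_expression(expr: ExpressionMatrix, values_path: str | Path, info_path: str | Path) -> None:
    expr.values.rename_axis("sample").to_csv(values_path, sep="\t", float_format="%.12g")
    expr.sample_info.rename_axis("sample").to_csv(info_path, sep="\t")


def read_expression(values_path: str | Path, info_path: str | Path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="sample")
    info = pd.read_csv(info_path, sep="\t", index_col="sample", keep_default_na=False)
    return ExpressionMatrix(values=values, sample_info=info)
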