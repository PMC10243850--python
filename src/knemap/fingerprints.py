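"""Exposure fingerprints: FCP scoring, gene selection, and feature vectors.

Every exposure (compound x biological system) is summarized by its most
deregulated genes, ranked by the FCP score

    FCP = logFC * (-log10(p-value))

which combines effect size and significance with the sign of the fold
change. After restricting to genes present in the prior network, the 100
most positive and 100 most negative FCP genes are selected and turned into
one of four representations:

* the community-fraction vector (the method's own fingerprint): for each
  prior-network community, the fraction of the selected genes falling into
  it;
* BDG, a binary indicator vector of the selection over the measured-gene
  universe;
* FC, the raw FCP values over a common gene ordering;
* GSEA, a vector of preranked gene-set-enrichment p-values of the selection
  against every other exposure's FCP-ranked list in the same system.

A Welch two-sample t-test on replicate expression values stands in for a
full linear-model differential-expression pipeline so that the noise and
stability experiments are executable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .community_detection import CommunityPartition

__all__ = [
    "DEProfile",
    "GeneSelection",
    "ExpressionMatrix",
    "compute_fcp",
    "select_deregulated",
    "knemap_vector",
    "bdg_vector",
    "fc_vector",
    "gsea_enrichment",
    "gsea_vector",
    "differential_profile",
]

P_FLOOR = 1e-300


def compute_fcp(logfc, pvalue, base: float = 10.0):
    """FCP score: logFC * (-log(p)), log base 10 by default.

    P-values must lie in (0, 1]; values below 1e-300 are clamped to that
    floor before taking the log. Scalar or array-like inputs are accepted.
    The base changes only magnitudes, never rankings.
    """
    p = np.asarray(pvalue, dtype=float)
    lfc = np.asarray(logfc, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must be in (0, 1]")
    p = np.clip(p, P_FLOOR, 1.0)
    out = lfc * (-np.log(p) / np.log(base))
    # -log(1.0) is -0.0; normalize so FCP at p=1 compares equal to 0 cleanly
    out = out + 0.0
    return float(out) if out.ndim == 0 else out


@dataclass
class DEProfile:
    """Differential-expression profile of one exposure on one system.

    ``table`` is indexed by gene symbol with columns ``logFC`` and
    ``pvalue``; one row per gene, p-values in (0, 1].
    """

    exposure_id: str
    system_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if not {"logFC", "pvalue"}.issubset(t.columns):
            raise ValueError("DEProfile table needs columns logFC, pvalue")
        if t.index.has_duplicates:
            raise ValueError("duplicate gene rows in DEProfile")
        p = t["pvalue"].to_numpy(dtype=float)
        if np.any(p <= 0) or np.any(p > 1):
            raise ValueError("p-values must be in (0, 1]")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def fcp(self, base: float = 10.0) -> pd.Series:
        return pd.Series(
            compute_fcp(self.table["logFC"].to_numpy(), self.table["pvalue"].to_numpy(), base),
            index=self.table.index,
            name="fcp",
        )


@dataclass
class GeneSelection:
    """Most deregulated network genes: up (most positive FCP first) and down
    (most negative first), disjoint, never padded across the zero boundary."""

    up: list[str]
    down: list[str]
    n_up: int = 100
    n_down: int = 100

    @property
    def genes(self) -> list[str]:
        return self.up + self.down

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.up) | frozenset(self.down)

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


def select_deregulated(
    profile: DEProfile,
    network_genes: set[str],
    n_up: int = 100,
    n_down: int = 100,
    base: float = 10.0,
) -> GeneSelection:
    """Select the most deregulated genes that are present in the prior network.

    The profile is restricted to ``network_genes`` *before* ranking, so a
    strongly deregulated gene absent from the network never enters the
    selection. Genes are sorted by FCP; the first ``n_up`` with FCP > 0 form
    the up list and the ``n_down`` most negative form the down list. If fewer
    genes qualify on a side, fewer are taken — zero-FCP genes are never used
    as padding. Ties are broken by |logFC| descending, then symbol ascending.
    """
    t = profile.table.loc[profile.table.index.isin(network_genes)].copy()
    if t.empty:
        raise ValueError(
            f"no genes of profile {profile.exposure_id!r} are in the prior network"
        )
    t["fcp"] = compute_fcp(t["logFC"].to_numpy(), t["pvalue"].to_numpy(), base)
    t["abs_lfc"] = t["logFC"].abs()
    t = (
        t.rename_axis("gene")
        .reset_index()
        .sort_values(["fcp", "abs_lfc", "gene"], ascending=[False, False, True], kind="mergesort")
    )
    pos = t[t["fcp"] > 0]
    neg = t[t["fcp"] < 0].sort_values(
        ["fcp", "abs_lfc", "gene"], ascending=[True, False, True], kind="mergesort"
    )
    return GeneSelection(
        up=pos["gene"].head(n_up).tolist(),
        down=neg["gene"].head(n_down).tolist(),
        n_up=n_up,
        n_down=n_down,
    )


def knemap_vector(sel: GeneSelection, partition: CommunityPartition) -> np.ndarray:
    """Fraction of the selected genes falling into each community.

    The vector spans *all* communities of the partition (zeros allowed) and
    sums to 1 whenever the selection is non-empty.
    """
    n_comm = partition.n_communities
    counts = np.zeros(n_comm)
    genes = sel.genes
    if not genes:
        return counts
    for g in genes:
        if g not in partition.assignment:
            raise ValueError(f"selected gene {g!r} is not in the partition")
        counts[partition.assignment[g]] += 1
    return counts / len(genes)


def bdg_vector(sel: GeneSelection, universe: list[str]) -> np.ndarray:
    """Binary deregulated-gene vector over a fixed gene universe."""
    idx = {g: i for i, g in enumerate(universe)}
    bits = np.zeros(len(universe))
    for g in sel.genes:
        if g not in idx:
            raise ValueError(f"selected gene {g!r} outside the universe")
        bits[idx[g]] = 1.0
    return bits


def fc_vector(profile: DEProfile, common_genes: list[str], base: float = 10.0) -> np.ndarray:
    """FCP values over the shared, fixed gene ordering."""
    missing = [g for g in common_genes if g not in profile.table.index]
    if missing:
        raise ValueError(f"genes missing from profile: {missing[:5]}")
    sub = profile.table.loc[common_genes]
    return np.asarray(compute_fcp(sub["logFC"].to_numpy(), sub["pvalue"].to_numpy(), base))


def gsea_enrichment(
    gene_set: set[str] | frozenset[str],
    ranked: DEProfile,
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    base: float = 10.0,
) -> tuple[float, float]:
    """Preranked GSEA: weighted Kolmogorov-Smirnov enrichment of a gene set.

    Genes are ranked by FCP descending. Walking down the list, hitting a
    set member increments the running sum by |FCP|^weight_exponent
    (normalized over the set), and a miss decrements by 1/(N - n). The
    enrichment score ES is the signed maximum deviation of the running sum.
    Significance comes from gene-label permutations: random sets of the same
    size, with

        p = (1 + #{ |ES*| >= |ES| }) / (1 + n_perm)

    Deterministic given the seed. When all set members carry zero FCP the
    hit increments fall back to the unweighted 1/n step.
    """
    if not gene_set:
        raise ValueError("empty gene set")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fcp = ranked.fcp(base)
    order = np.lexsort((fcp.index.to_numpy(), -fcp.to_numpy()))
    genes = fcp.index.to_numpy()[order]
    scores = fcp.to_numpy()[order]
    member = np.isin(genes, list(gene_set))
    n = int(member.sum())
    if n != len(gene_set):
        missing = sorted(set(gene_set) - set(genes))
        raise ValueError(f"gene set members missing from the ranked list: {missing[:5]}")
    N = len(genes)
    if n >= N:
        raise ValueError("gene set cannot cover the whole ranked list")
    w = np.abs(scores) ** weight_exponent

    def _es(hit_mask: np.ndarray) -> float:
        hit_w = np.where(hit_mask, w, 0.0)
        total = hit_w.sum()
        if total > 0:
            inc = hit_w / total
        else:
            inc = np.where(hit_mask, 1.0 / n, 0.0)
        dec = np.where(hit_mask, 0.0, 1.0 / (N - n))
        running = np.cumsum(inc - dec)
        i = int(np.argmax(np.abs(running)))
        return float(running[i])

    es = _es(member)

    # vectorized label permutations: each row is a random size-n hit mask
    pos = np.argsort(rng.random((n_perm, N)), axis=1)[:, :n]
    masks = np.zeros((n_perm, N), dtype=bool)
    np.put_along_axis(masks, pos, True, axis=1)
    hit_w = np.where(masks, w[None, :], 0.0)
    totals = hit_w.sum(axis=1)
    inc = np.empty_like(hit_w)
    ok = totals > 0
    inc[ok] = hit_w[ok] / totals[ok, None]
    inc[~ok] = np.where(masks[~ok], 1.0 / n, 0.0)
    dec = np.where(masks, 0.0, 1.0 / (N - n))
    running = np.cumsum(inc - dec, axis=1)
    es_perm = np.take_along_axis(
        running, np.argmax(np.abs(running), axis=1)[:, None], axis=1
    )[:, 0]
    pvalue = (1 + int(np.sum(np.abs(es_perm) >= abs(es)))) / (1 + n_perm)
    return es, float(pvalue)


def gsea_vector(
    target: str,
    profiles: list[DEProfile],
    network_genes: set[str] | None = None,
    n_up: int = 100,
    n_down: int = 100,
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    base: float = 10.0,
) -> tuple[list[str], np.ndarray]:
    """Enrichment p-values of one exposure's selection against all others.

    The target's top deregulated genes (its GeneSelection as a set) are
    tested against the FCP-ranked list of every *other* exposure in the same
    system; the references are ordered by exposure id so vectors are
    comparable across targets. Returns (reference ids, p-value vector).
    Child RNG streams are derived per reference, so each entry is
    independent of the order in which references are processed.
    """
    by_id = {p.exposure_id: p for p in profiles}
    if target not in by_id:
        raise ValueError(f"unknown target exposure {target!r}")
    if len(by_id) < 2:
        raise ValueError("need at least 2 exposures in the system")
    systems = {p.system_id for p in profiles}
    if len(systems) != 1:
        raise ValueError("all profiles must come from the same system")
    tgt = by_id[target]
    universe = set(tgt.genes) if network_genes is None else network_genes
    sel = select_deregulated(tgt, universe, n_up=n_up, n_down=n_down, base=base)
    refs = sorted(r for r in by_id if r != target)
    pvals = np.empty(len(refs))
    ss = np.random.SeedSequence(seed)
    children = {r: c for r, c in zip(refs, ss.spawn(len(refs)))}
    for i, r in enumerate(refs):
        gene_set = sel.gene_set & set(by_id[r].genes)
        if not gene_set:
            raise ValueError(f"target selection shares no genes with {r!r}")
        _, pvals[i] = gsea_enrichment(
            gene_set,
            by_id[r],
            weight_exponent=weight_exponent,
            n_perm=n_perm,
            seed=np.random.default_rng(children[r]),
            base=base,
        )
    return refs, pvals


@dataclass
class ExpressionMatrix:
    """Replicate-level expression values with sample annotations.

    ``values`` is samples x genes (log-like additive scale assumed);
    ``sample_info`` is indexed like ``values`` with columns ``system``,
    ``exposure`` and ``group`` in {control, treated}. Control samples of a
    system carry an empty exposure field and are shared by its exposures.
    """

    values: pd.DataFrame
    sample_info: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.sample_info.index):
            raise ValueError("values and sample_info must share the sample index")
        need = {"system", "exposure", "group"}
        if not need.issubset(self.sample_info.columns):
            raise ValueError(f"sample_info needs columns {sorted(need)}")
        bad = set(self.sample_info["group"]) - {"control", "treated"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    def systems(self) -> list[str]:
        return sorted(self.sample_info["system"].unique())

    def exposures(self, system: str) -> list[str]:
        info = self.sample_info
        mask = (info["system"] == system) & (info["group"] == "treated")
        return sorted(info.loc[mask, "exposure"].unique())

    def controls(self, system: str) -> pd.DataFrame:
        info = self.sample_info
        mask = (info["system"] == system) & (info["group"] == "control")
        return self.values.loc[mask]

    def treated(self, system: str, exposure: str) -> pd.DataFrame:
        info = self.sample_info
        mask = (
            (info["system"] == system)
            & (info["exposure"] == exposure)
            & (info["group"] == "treated")
        )
        return self.values.loc[mask]


def differential_profile(expr: ExpressionMatrix, system: str, exposure: str) -> DEProfile:
    """Welch t-test stand-in for a full differential-expression fit.

    Per gene: logFC = mean(treated) - mean(control) (log-scale input
    assumed) and a two-sided Welch t-test p-value, floored at 1e-300.
    Degenerate genes with zero variance in both groups get p = 1.
    """
    ctrl = expr.controls(system)
    trt = expr.treated(system, exposure)
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValueError(
            f"need >=2 replicates per group for {system}/{exposure} "
            f"(got {len(ctrl)} control, {len(trt)} treated)"
        )
    a = trt.to_numpy(dtype=float)
    b = ctrl.to_numpy(dtype=float)
    logfc = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=0, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)
    p = np.clip(p, P_FLOOR, 1.0)
    table = pd.DataFrame({"logFC": logfc, "pvalue": p}, index=expr.values.columns)
    table.index.name = "gene"
    return DEProfile(exposure_id=exposure, system_id=system, table=table)
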