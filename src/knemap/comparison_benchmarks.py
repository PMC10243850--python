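"""Benchmark machinery for comparing exposure representations.

Contains every pairwise-comparison tool used to evaluate the
community-fraction fingerprint against its baselines (BDG, FC, GSEA):

* cosine-distance / Pearson similarity matrices and compound clustering per
  biological system, with cross-system cluster overlap via Jaccard indices;
* functional retrieval curves against compound class labels (emulating ATC
  level-3 pharmacological groups);
* structural rank agreement against a reference ranking built from
  Levenshtein distances on structure strings (emulating SMILES) or cosine
  distances on descriptor vectors;
* two noise experiments — Gaussian noise on replicate expression values and
  random replacement of selected genes — measuring each method's mean
  cosine distance to its noise-free baseline;
* the stable-gene-subset stability check and cross-dataset mean-rank
  matching.

AUCs are trapezoidal on the stated x-grids without normalization, so they
are comparable across methods evaluated on the same grid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .community_detection import CommunityPartition
from .fingerprints import (
    DEProfile,
    ExpressionMatrix,
    GeneSelection,
    bdg_vector,
    differential_profile,
    fc_vector,
    gsea_vector,
    knemap_vector,
    select_deregulated,
)

__all__ = [
    "SimilarityMatrix",
    "CompoundClustering",
    "ClusterOverlap",
    "RetrievalCurve",
    "PairRanking",
    "RankAgreement",
    "NoiseCurve",
    "CrossDatasetMatch",
    "FingerprintContext",
    "cosine_distance",
    "pairwise_similarity",
    "cluster_compounds",
    "cluster_overlap",
    "class_retrieval_curve",
    "mean_retrieval_curve",
    "levenshtein",
    "reference_pair_ranking",
    "rank_agreement",
    "gaussian_noise_experiment",
    "replacement_noise_experiment",
    "subset_stability",
    "cross_dataset_match",
]


# ---------------------------------------------------------------------------
# similarity matrices and compound clustering


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine distance 1 - cos(u, v) with an explicit zero-vector rule.

    Two zero vectors are at distance 0; a zero vector against a non-zero one
    is at distance 1 (no shared direction), so benchmark loops never see NaN.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vector length mismatch")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 and nv == 0:
        return 0.0
    if nu == 0 or nv == 0:
        return 1.0
    return float(1.0 - np.dot(u, v) / (nu * nv))


@dataclass
class SimilarityMatrix:
    ids: list[str]
    values: np.ndarray
    metric: str  # cosine_distance | pearson

    def of(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])


def pairwise_similarity(
    ids: list[str], vectors: np.ndarray, metric: str = "cosine_distance"
) -> SimilarityMatrix:
    """All-pairs cosine distance or Pearson correlation between row vectors."""
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[0] != len(ids):
        raise ValueError("vectors must be a 2D array with one row per id")
    if vectors.shape[0] < 2:
        raise ValueError("need at least 2 vectors")
    n = len(ids)
    M = np.zeros((n, n))
    if metric == "cosine_distance":
        for i in range(n):
            for j in range(i + 1, n):
                M[i, j] = M[j, i] = cosine_distance(vectors[i], vectors[j])
    elif metric == "pearson":
        np.fill_diagonal(M, 1.0)
        for i in range(n):
            for j in range(i + 1, n):
                si, sj = np.std(vectors[i]), np.std(vectors[j])
                if si == 0 or sj == 0:
                    r = 0.0
                else:
                    r = float(np.corrcoef(vectors[i], vectors[j])[0, 1])
                M[i, j] = M[j, i] = r
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return SimilarityMatrix(ids=list(ids), values=M, metric=metric)


@dataclass
class CompoundClustering:
    system_id: str
    assignment: dict[str, int]
    k: int

    def members(self, cluster: int) -> set[str]:
        return {e for e, c in self.assignment.items() if c == cluster}


def cluster_compounds(sim: SimilarityMatrix, k: int, system_id: str = "") -> CompoundClustering:
    """Ward hierarchical clustering of exposures on their cosine distances."""
    n = len(sim.ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    if sim.metric != "cosine_distance":
        raise ValueError("cluster_compounds expects a cosine_distance matrix")
    if k == n:
        labels = np.arange(n) + 1
    else:
        Z = linkage(squareform(sim.values, checks=False), method="ward")
        labels = fcluster(Z, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for e, lab in zip(sim.ids, labels):
        if lab not in remap:
            remap[int(lab)] = len(remap)
        assignment[e] = remap[int(lab)]
    return CompoundClustering(system_id=system_id, assignment=assignment, k=len(remap))


@dataclass
class ClusterOverlap:
    """Jaccard overlap between the clusters of two systems' clusterings."""

    jaccard: np.ndarray  # clusters of a x clusters of b
    clusters_a: list[int]
    clusters_b: list[int]
    best_match: dict[int, tuple[int, float]]  # cluster of a -> (cluster of b, J)
    consistent_exposures: set[str]


def cluster_overlap(
    a: CompoundClustering, b: CompoundClustering, threshold: float = 0.5
) -> ClusterOverlap:
    """Compare two per-system compound clusterings via the Jaccard index.

    For every cluster pair J = |members_a n members_b| / |members_a u
    members_b|; each cluster of ``a`` is matched to its best-overlapping
    cluster of ``b``, and exposures in matched pairs with J >= threshold form
    the cross-system consistent set.
    """
    if not set(a.assignment) & set(b.assignment):
        raise ValueError("clusterings share no exposures")
    ca = sorted(set(a.assignment.values()))
    cb = sorted(set(b.assignment.values()))
    J = np.zeros((len(ca), len(cb)))
    for i, ci in enumerate(ca):
        ma = a.members(ci)
        for j, cj in enumerate(cb):
            mb = b.members(cj)
            J[i, j] = len(ma & mb) / len(ma | mb)
    best: dict[int, tuple[int, float]] = {}
    consistent: set[str] = set()
    for i, ci in enumerate(ca):
        j = int(np.argmax(J[i]))
        best[ci] = (cb[j], float(J[i, j]))
        if J[i, j] >= threshold:
            consistent |= a.members(ci) & b.members(cb[j])
    return ClusterOverlap(
        jaccard=J, clusters_a=ca, clusters_b=cb, best_match=best, consistent_exposures=consistent
    )


# ---------------------------------------------------------------------------
# class retrieval


@dataclass
class RetrievalCurve:
    x: np.ndarray
    scores: dict[str, np.ndarray]  # method -> curve over x
    auc: dict[str, float]


def _trapz(y: np.ndarray, x: np.ndarray) -> float:
    return float(np.trapezoid(y, x))


def class_retrieval_curve(
    vectors_per_method: dict[str, tuple[list[str], np.ndarray]],
    class_labels: dict[str, str],
    x_max: int | None = None,
) -> RetrievalCurve:
    """Functional retrieval against compound class labels.

    For every labeled compound c, the other labeled compounds are ranked by
    Pearson similarity of their vectors (descending). score_c(x) is the
    number of same-class compounds in the top x divided by the class size in
    the dataset excluding c itself (a compound cannot retrieve itself); the
    reported curve at x is the sum of score_c(x) over all c. Compounds whose
    class has no other member contribute 0 throughout.
    """
    curves: dict[str, np.ndarray] = {}
    auc: dict[str, float] = {}
    x_grid: np.ndarray | None = None
    for method, (ids, vectors) in vectors_per_method.items():
        labeled = [e for e in ids if e in class_labels]
        if len(labeled) < 2:
            raise ValueError("need at least 2 labeled compounds")
        sim = pairwise_similarity(
            labeled, np.asarray(vectors)[[ids.index(e) for e in labeled]], metric="pearson"
        )
        n = len(labeled)
        hi = min(x_max or (n - 1), n - 1)
        xs = np.arange(1, hi + 1)
        total = np.zeros(hi)
        for ci, c in enumerate(labeled):
            mates = [e for e in labeled if e != c and class_labels[e] == class_labels[c]]
            if not mates:
                continue
            others = [e for e in labeled if e != c]
            order = sorted(others, key=lambda e: (-sim.of(c, e), e))
            same = np.array([class_labels[e] == class_labels[c] for e in order], dtype=float)
            hits = np.cumsum(same)[:hi]
            total += hits / len(mates)
        curves[method] = total
        auc[method] = _trapz(total, xs)
        x_grid = xs
    assert x_grid is not None
    return RetrievalCurve(x=x_grid, scores=curves, auc=auc)


def mean_retrieval_curve(curves: list[RetrievalCurve]) -> RetrievalCurve:
    """Average retrieval curves across biological systems (shared grid)."""
    if not curves:
        raise ValueError("no curves")
    hi = min(len(c.x) for c in curves)
    x = curves[0].x[:hi]
    methods = curves[0].scores.keys()
    scores = {
        m: np.mean([c.scores[m][:hi] for c in curves], axis=0) for m in methods
    }
    return RetrievalCurve(x=x, scores=scores, auc={m: _trapz(s, x) for m, s in scores.items()})


# ---------------------------------------------------------------------------
# structural reference ranking and rank agreement


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insert / delete / substitute)."""
    return int(edlib.align(a, b, task="distance")["editDistance"])


@dataclass
class PairRanking:
    """Unordered exposure pairs ranked ascending by a distance (rank 1 =
    most similar); ties carry their average rank."""

    pairs: list[tuple[str, str]]
    distances: np.ndarray
    ranks: np.ndarray

    def rank_of(self) -> dict[tuple[str, str], float]:
        return {p: float(r) for p, r in zip(self.pairs, self.ranks)}

    def top(self, x: int) -> list[tuple[str, str]]:
        order = sorted(range(len(self.pairs)), key=lambda i: (self.ranks[i], self.pairs[i]))
        return [self.pairs[i] for i in order[:x]]


def _make_pair_ranking(pairs: list[tuple[str, str]], dists: np.ndarray) -> PairRanking:
    return PairRanking(pairs=pairs, distances=dists, ranks=rankdata(dists, method="average"))


def reference_pair_ranking(structures: dict[str, str | np.ndarray]) -> PairRanking:
    """Reference ranking of exposure pairs from structural annotations.

    String annotations are compared by Levenshtein distance; numeric
    descriptor vectors by cosine distance. Pairs are ranked ascending, so
    rank 1 is the structurally most similar pair.
    """
    ids = sorted(structures)
    if len(ids) < 2:
        raise ValueError("need at least 2 annotated exposures")
    pairs: list[tuple[str, str]] = []
    dists: list[float] = []
    for a, b in itertools.combinations(ids, 2):
        sa, sb = structures[a], structures[b]
        if isinstance(sa, str) and isinstance(sb, str):
            d = float(levenshtein(sa, sb))
        else:
            d = cosine_distance(np.asarray(sa, dtype=float), np.asarray(sb, dtype=float))
        pairs.append((a, b))
        dists.append(d)
    return _make_pair_ranking(pairs, np.asarray(dists))


def method_pair_ranking(sim: SimilarityMatrix, restrict: set[str] | None = None) -> PairRanking:
    """Rank exposure pairs of a cosine-distance matrix, most similar first."""
    if sim.metric != "cosine_distance":
        raise ValueError("pair ranking expects cosine distances")
    ids = sorted(restrict & set(sim.ids)) if restrict is not None else sorted(sim.ids)
    pairs: list[tuple[str, str]] = []
    dists: list[float] = []
    for a, b in itertools.combinations(ids, 2):
        pairs.append((a, b))
        dists.append(sim.of(a, b))
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    return _make_pair_ranking(pairs, np.asarray(dists))


@dataclass
class RankAgreement:
    x_diff: np.ndarray
    mean_rank_difference: np.ndarray
    auc_rank_difference: float
    x_jac: np.ndarray
    jaccard: np.ndarray
    auc_jaccard: float
    top20_rank_differences: np.ndarray


def rank_agreement(
    method: PairRanking,
    reference: PairRanking,
    x_diff: tuple[int, int] = (2, 200),
    x_jac: tuple[int, int] = (1, 1000),
) -> RankAgreement:
    """Agreement of a method's pair ranking with the structural reference.

    Two complementary curves: the mean absolute rank difference over the
    method's top-x pairs (x from 2 to 200; lower AUC = more agreement) and
    the Jaccard index between the method's and the reference's top-x pair
    sets (x from 1 to 1000; higher AUC = more agreement). Grids are
    truncated to the number of available pairs. A sample of the top-20 rank
    differences is retained for density reporting.
    """
    if set(method.pairs) != set(reference.pairs):
        raise ValueError("method and reference must rank the same pair universe")
    n_pairs = len(method.pairs)
    if n_pairs < 2:
        raise ValueError("need at least 2 pairs")
    ref_rank = reference.rank_of()
    ordered = method.top(n_pairs)
    diffs = np.array([abs(method.rank_of()[p] - ref_rank[p]) for p in ordered])

    lo_d, hi_d = x_diff
    hi_d = min(hi_d, n_pairs)
    xs_d = np.arange(lo_d, hi_d + 1)
    csum = np.cumsum(diffs)
    mean_diff = np.array([csum[x - 1] / x for x in xs_d])

    lo_j, hi_j = x_jac
    hi_j = min(hi_j, n_pairs)
    xs_j = np.arange(lo_j, hi_j + 1)
    ref_ordered = reference.top(n_pairs)
    jac = np.empty(len(xs_j))
    for i, x in enumerate(xs_j):
        a, b = set(ordered[:x]), set(ref_ordered[:x])
        jac[i] = len(a & b) / len(a | b)
    return RankAgreement(
        x_diff=xs_d,
        mean_rank_difference=mean_diff,
        auc_rank_difference=_trapz(mean_diff, xs_d),
        x_jac=xs_j,
        jaccard=jac,
        auc_jaccard=_trapz(jac, xs_j),
        top20_rank_differences=diffs[: min(20, n_pairs)],
    )


# ---------------------------------------------------------------------------
# noise experiments


@dataclass
class FingerprintContext:
    """Everything needed to rebuild exposure vectors inside an experiment."""

    partition: CommunityPartition
    network_genes: set[str]
    universe: list[str]  # measured genes, fixed order (BDG / FC baseline)
    n_up: int = 100
    n_down: int = 100
    gsea_n_perm: int = 200
    gsea_weight_exponent: float = 1.0
    gsea_seed: int = 0


@dataclass
class NoiseCurve:
    levels: np.ndarray
    mean: dict[str, np.ndarray]  # method -> mean cosine distance per level
    sd: dict[str, np.ndarray]
    auc: dict[str, float]


def _vectors_for_system(
    profiles: list[DEProfile], methods: list[str], ctx: FingerprintContext
) -> dict[str, dict[str, np.ndarray]]:
    """Per-method, per-exposure vectors for one system's profiles."""
    out: dict[str, dict[str, np.ndarray]] = {m: {} for m in methods}
    selections = {
        p.exposure_id: select_deregulated(p, ctx.network_genes, ctx.n_up, ctx.n_down)
        for p in profiles
    }
    for p in profiles:
        sel = selections[p.exposure_id]
        if "knemap" in methods:
            out["knemap"][p.exposure_id] = knemap_vector(sel, ctx.partition)
        if "bdg" in methods:
            out["bdg"][p.exposure_id] = bdg_vector(sel, ctx.universe)
        if "fc" in methods:
            out["fc"][p.exposure_id] = fc_vector(p, ctx.universe)
    if "gsea" in methods:
        for p in profiles:
            _, pv = gsea_vector(
                p.exposure_id,
                profiles,
                network_genes=ctx.network_genes,
                n_up=ctx.n_up,
                n_down=ctx.n_down,
                weight_exponent=ctx.gsea_weight_exponent,
                n_perm=ctx.gsea_n_perm,
                seed=ctx.gsea_seed,
            )
            out["gsea"][p.exposure_id] = pv
    return out


def gaussian_noise_experiment(
    expr: ExpressionMatrix,
    ctx: FingerprintContext,
    sigmas: list[float] | None = None,
    methods: list[str] | None = None,
    seed: int = 0,
) -> NoiseCurve:
    """Robustness to additive Gaussian noise on the expression values.

    For every noise level sigma, i.i.d. N(0, sigma) noise is added to every
    sample entry, differential profiles are recomputed with the Welch
    stand-in, each method's vectors are rebuilt, and the cosine distance of
    every exposure to its noise-free baseline vector is measured. The curve
    reports mean and standard deviation across exposures per level and a
    trapezoidal AUC per method. Level 0 anchors the curve at distance 0.

    Noise levels are coupled by common random numbers: one standard-normal
    field Z is drawn from the seed and the level-sigma perturbation is
    sigma * Z. Each level still receives exact N(0, sigma^2) noise, but the
    comparison across levels isolates the effect of the noise magnitude
    from resampling variance, which at desk scale would otherwise swamp
    the level-to-level differences.
    """
    if sigmas is None:
        sigmas = [0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
    if methods is None:
        methods = ["knemap", "fc", "gsea"]
    levels = np.asarray(sorted({0.0} | set(sigmas)))
    if np.any(levels < 0):
        raise ValueError("noise levels must be non-negative")
    Z = np.random.default_rng(seed).normal(size=expr.values.shape)

    def profiles_at(values: pd.DataFrame) -> dict[str, list[DEProfile]]:
        noisy = ExpressionMatrix(values=values, sample_info=expr.sample_info)
        return {
            s: [differential_profile(noisy, s, e) for e in noisy.exposures(s)]
            for s in noisy.systems()
        }

    baseline = {
        s: _vectors_for_system(ps, methods, ctx) for s, ps in profiles_at(expr.values).items()
    }
    mean: dict[str, list[float]] = {m: [] for m in methods}
    sd: dict[str, list[float]] = {m: [] for m in methods}
    for level in levels:
        if level == 0:
            per_system = baseline
        else:
            noisy_values = expr.values + level * Z
            per_system = {
                s: _vectors_for_system(ps, methods, ctx)
                for s, ps in profiles_at(noisy_values).items()
            }
        for m in methods:
            dists = [
                cosine_distance(per_system[s][m][e], baseline[s][m][e])
                for s in baseline
                for e in baseline[s][m]
            ]
            mean[m].append(float(np.mean(dists)))
            sd[m].append(float(np.std(dists)))
    return NoiseCurve(
        levels=levels,
        mean={m: np.asarray(v) for m, v in mean.items()},
        sd={m: np.asarray(v) for m, v in sd.items()},
        auc={m: _trapz(np.asarray(v), levels) for m, v in mean.items()},
    )


def _replace_selection(
    sel: GeneSelection, prob: float, universe: list[str], rng: np.random.Generator
) -> GeneSelection:
    """Replace each selected gene w.p. ``prob`` by a random universe gene.

    Draws exclude genes currently in the selection, so replacement at high
    probability is never a silent no-op and the selection size is conserved.
    """
    current = set(sel.genes)
    new_up, new_down = list(sel.up), list(sel.down)
    for lst in (new_up, new_down):
        for i, g in enumerate(lst):
            if rng.random() < prob:
                candidates = [u for u in universe if u not in current]
                if not candidates:
                    raise ValueError("universe too small for replacement")
                repl = candidates[int(rng.integers(len(candidates)))]
                current.discard(g)
                current.add(repl)
                lst[i] = repl
    return GeneSelection(up=new_up, down=new_down, n_up=sel.n_up, n_down=sel.n_down)


def replacement_noise_experiment(
    selections: dict[str, GeneSelection],
    ctx: FingerprintContext,
    profiles: list[DEProfile] | None = None,
    probs: list[float] | None = None,
    methods: list[str] | None = None,
    seed: int = 0,
) -> NoiseCurve:
    """Robustness to random replacement of the selected deregulated genes.

    Each gene of every exposure's selection is replaced, with probability p,
    by a uniformly drawn gene from the measured universe not currently in
    the selection; the vectors are rebuilt from the perturbed selections and
    compared with the unperturbed baseline by cosine distance. GSEA vectors
    need the per-exposure ranked profiles of the same system, passed via
    ``profiles``.
    """
    if probs is None:
        probs = [0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
    if methods is None:
        methods = ["knemap", "bdg"]
    if "gsea" in methods and profiles is None:
        raise ValueError("gsea replacement noise needs the ranked profiles")
    levels = np.asarray(sorted({0.0} | set(probs)))
    if np.any((levels < 0) | (levels > 1)):
        raise ValueError("replacement probabilities must be in [0, 1]")
    by_id = {p.exposure_id: p for p in (profiles or [])}

    def vecs(sel_map: dict[str, GeneSelection]) -> dict[str, dict[str, np.ndarray]]:
        out: dict[str, dict[str, np.ndarray]] = {m: {} for m in methods}
        for e, sel in sel_map.items():
            if "knemap" in methods:
                out["knemap"][e] = knemap_vector(sel, ctx.partition)
            if "bdg" in methods:
                out["bdg"][e] = bdg_vector(sel, ctx.universe)
            if "gsea" in methods:
                refs = sorted(r for r in sel_map if r != e)
                ss = np.random.SeedSequence(ctx.gsea_seed)
                kids = {r: c for r, c in zip(refs, ss.spawn(len(refs)))}
                from .fingerprints import gsea_enrichment

                pv = np.empty(len(refs))
                for i, r in enumerate(refs):
                    gene_set = sel.gene_set & set(by_id[r].genes)
                    _, pv[i] = gsea_enrichment(
                        gene_set,
                        by_id[r],
                        weight_exponent=ctx.gsea_weight_exponent,
                        n_perm=ctx.gsea_n_perm,
                        seed=np.random.default_rng(kids[r]),
                    )
                out["gsea"][e] = pv
        return out

    baseline = vecs(selections)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(levels))
    mean: dict[str, list[float]] = {m: [] for m in methods}
    sd: dict[str, list[float]] = {m: [] for m in methods}
    for level, child in zip(levels, children):
        if level == 0:
            per = baseline
        else:
            rng = np.random.default_rng(child)
            perturbed = {
                e: _replace_selection(sel, float(level), ctx.universe, rng)
                for e, sel in sorted(selections.items())
            }
            per = vecs(perturbed)
        for m in methods:
            dists = [cosine_distance(per[m][e], baseline[m][e]) for e in sorted(selections)]
            mean[m].append(float(np.mean(dists)))
            sd[m].append(float(np.std(dists)))
    return NoiseCurve(
        levels=levels,
        mean={m: np.asarray(v) for m, v in mean.items()},
        sd={m: np.asarray(v) for m, v in sd.items()},
        auc={m: _trapz(np.asarray(v), levels) for m, v in mean.items()},
    )


# ---------------------------------------------------------------------------
# stability across gene subsets


def flag_unstable_genes(expr: ExpressionMatrix, alpha: float = 0.05) -> set[str]:
    """Genes differentially expressed between the control samples of at
    least one pair of biological systems (Welch t-test, p < alpha)."""
    systems = expr.systems()
    if len(systems) < 2:
        raise ValueError("need >= 2 systems with control replicates")
    flagged: set[str] = set()
    genes = np.asarray(expr.genes)
    from scipy import stats

    for sa, sb in itertools.combinations(systems, 2):
        a = expr.controls(sa).to_numpy(dtype=float)
        b = expr.controls(sb).to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"need >= 2 control replicates in {sa} and {sb}")
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.asarray(stats.ttest_ind(a, b, axis=0, equal_var=False).pvalue, dtype=float)
        p = np.where(np.isnan(p), 1.0, p)
        flagged |= set(genes[p < alpha])
    return flagged


def subset_stability(
    expr: ExpressionMatrix,
    profiles: dict[str, list[DEProfile]],
    ctx: FingerprintContext,
    alpha: float = 0.05,
) -> dict:
    """Stability of the community fingerprint under steady-state differences.

    Genes differentially expressed between control samples of any system
    pair are removed, fingerprints are recomputed on the stable subset, and
    the per-exposure-pair cosine distances are compared with the
    full-universe ones. A distribution of differences centered near zero
    means the fingerprint is robust to baseline expression differences
    between systems.
    """
    unstable = flag_unstable_genes(expr, alpha)
    stable_network = ctx.network_genes - unstable
    if not stable_network:
        raise ValueError("no stable network genes remain")
    diffs: list[float] = []
    for system, plist in sorted(profiles.items()):
        full = {}
        sub = {}
        for p in plist:
            sel_full = select_deregulated(p, ctx.network_genes, ctx.n_up, ctx.n_down)
            sel_sub = select_deregulated(p, stable_network, ctx.n_up, ctx.n_down)
            full[p.exposure_id] = knemap_vector(sel_full, ctx.partition)
            sub[p.exposure_id] = knemap_vector(sel_sub, ctx.partition)
        for a, b in itertools.combinations(sorted(full), 2):
            d_full = cosine_distance(full[a], full[b])
            d_sub = cosine_distance(sub[a], sub[b])
            diffs.append(d_full - d_sub)
    arr = np.asarray(diffs)
    return {
        "differences": arr,
        "n_pairs": len(arr),
        "median": float(np.median(arr)),
        "mean": float(np.mean(arr)),
        "n_unstable_genes": len(unstable),
        "n_stable_network_genes": len(stable_network),
    }


# ---------------------------------------------------------------------------
# cross-dataset matching


@dataclass
class CrossDatasetMatch:
    mean_ranks: pd.DataFrame  # queries x candidates
    best_match: dict[str, str]
    # (query, query system, candidate system) -> candidates most similar first
    rankings: dict[tuple[str, str, str], list[str]]


def cross_dataset_match(
    query_vectors: dict[str, dict[str, np.ndarray]],
    candidate_vectors: dict[str, dict[str, np.ndarray]],
) -> CrossDatasetMatch:
    """Match each query exposure to its most similar candidate across systems.

    Both datasets must be fingerprinted against the same community partition
    (enforced by equal vector lengths). For every (query system, candidate
    system) combination, candidates are ranked by cosine distance to the
    query ascending; the mean of a candidate's ranks across combinations is
    its score, and the candidate with the minimal mean rank (ties broken by
    id) is the best match.
    """
    q_systems = sorted(query_vectors)
    c_systems = sorted(candidate_vectors)
    if not q_systems or not c_systems:
        raise ValueError("empty query or candidate set")
    lengths = {
        len(v)
        for d in (*query_vectors.values(), *candidate_vectors.values())
        for v in d.values()
    }
    if len(lengths) != 1:
        raise ValueError("vectors must share one partition (equal lengths)")
    queries = sorted({q for s in q_systems for q in query_vectors[s]})
    candidates = sorted({c for s in c_systems for c in candidate_vectors[s]})
    ranks = pd.DataFrame(0.0, index=queries, columns=candidates)
    counts = pd.DataFrame(0, index=queries, columns=candidates)
    rankings: dict[tuple[str, str, str], list[str]] = {}
    for qs in q_systems:
        for cs in c_systems:
            cand_ids = sorted(candidate_vectors[cs])
            for q, qvec in sorted(query_vectors[qs].items()):
                dists = np.array(
                    [cosine_distance(qvec, candidate_vectors[cs][c]) for c in cand_ids]
                )
                r = rankdata(dists, method="average")
                for c, rk in zip(cand_ids, r):
                    ranks.loc[q, c] += rk
                    counts.loc[q, c] += 1
                order = sorted(range(len(cand_ids)), key=lambda i: (dists[i], cand_ids[i]))
                rankings[(q, qs, cs)] = [cand_ids[i] for i in order]
    if (counts.to_numpy() == 0).any():
        raise ValueError("some query-candidate pair was never compared")
    mean_ranks = ranks / counts
    best = {
        q: min(candidates, key=lambda c: (mean_ranks.loc[q, c], c)) for q in queries
    }
    return CrossDatasetMatch(mean_ranks=mean_ranks, best_match=best, rankings=rankings)
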