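"""Independent brute-force / dynamic-programming oracles used by the tests.

Each oracle is a deliberately naive re-implementation of an operation,
kept free of any code path from the package so the two can disagree.
"""

from __future__ import annotations

import itertools

import numpy as np


def count_distinct_sources(triples):
    """Naive scan: weight of each unordered pair = distinct source labels."""
    out = {}
    for a, b, s in triples:
        key = (min(a, b), max(a, b))
        out.setdefault(key, set()).add(s)
    return {k: float(len(v)) for k, v in out.items()}


def shared_entity_counts(entities_by_gene):
    """Nested-loop |entities(a) & entities(b)| for every gene pair."""
    genes = sorted(entities_by_gene)
    out = {}
    for a, b in itertools.combinations(genes, 2):
        n = len(entities_by_gene[a] & entities_by_gene[b])
        if n:
            out[(a, b)] = float(n)
    return out


def naive_linkage_partition(D, threshold=None, n_clusters=None, linkage="single"):
    """Plain agglomerative clustering on a dense distance matrix.

    Merges the closest cluster pair while the linkage distance is strictly
    below ``threshold`` (or until ``n_clusters`` remain). Ward uses the
    Lance-Williams recurrence on squared distances. Returns a list of
    frozensets of item indices.
    """
    n = len(D)
    clusters = [frozenset([i]) for i in range(n)]
    if linkage == "ward":
        d = {(i, j): D[i, j] ** 2 for i in range(n) for j in range(i + 1, n)}
    else:
        d = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}

    def dist(ci, cj):
        key = (min(ci, cj), max(ci, cj))
        return d[key]

    active = list(range(n))
    members = {i: clusters[i] for i in active}
    next_id = n
    while len(active) > (n_clusters or 1):
        best = None
        for i, j in itertools.combinations(sorted(active), 2):
            dd = dist(i, j)
            if best is None or dd < best[0]:
                best = (dd, i, j)
        dd, i, j = best
        link_dist = np.sqrt(dd) if linkage == "ward" else dd
        if threshold is not None and link_dist >= threshold:
            break
        merged = members[i] | members[j]
        for k in active:
            if k in (i, j):
                continue
            dik, djk, dij = dist(i, k), dist(j, k), dist(i, j)
            if linkage == "single":
                new = min(dik, djk)
            elif linkage == "complete":
                new = max(dik, djk)
            elif linkage == "average":
                ni, nj = len(members[i]), len(members[j])
                new = (ni * dik + nj * djk) / (ni + nj)
            elif linkage == "ward":
                ni, nj, nk = len(members[i]), len(members[j]), len(members[k])
                new = ((ni + nk) * dik + (nj + nk) * djk - nk * dij) / (ni + nj + nk)
            else:
                raise ValueError(linkage)
            d[(min(next_id, k), max(next_id, k))] = new
        members[next_id] = merged
        active = [k for k in active if k not in (i, j)] + [next_id]
        del members[i], members[j]
        next_id += 1
    return [members[k] for k in active]


def gsea_walk(ranked_scores, member_flags, weight_exponent):
    """Step-by-step running-sum enrichment score on an explicit list."""
    N = len(ranked_scores)
    n = sum(member_flags)
    total = sum(abs(s) ** weight_exponent for s, m in zip(ranked_scores, member_flags) if m)
    running = 0.0
    best = 0.0
    for s, m in zip(ranked_scores, member_flags):
        if m:
            running += (abs(s) ** weight_exponent / total) if total > 0 else 1.0 / n
        else:
            running -= 1.0 / (N - n)
        if abs(running) > abs(best):
            best = running
    return best


def levenshtein_dp(a: str, b: str) -> int:
    """Classic O(len(a) * len(b)) dynamic-programming edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def retrieval_recount(sim_of, ids, labels, x_max):
    """Nested-loop recount of the class retrieval curve (summed over c)."""
    curve = np.zeros(x_max)
    for c in ids:
        mates = [e for e in ids if e != c and labels[e] == labels[c]]
        if not mates:
            continue
        order = sorted((e for e in ids if e != c), key=lambda e: (-sim_of(c, e), e))
        for x in range(1, x_max + 1):
            hits = sum(1 for e in order[:x] if labels[e] == labels[c])
            curve[x - 1] += hits / len(mates)
    return curve


def average_ranks(values):
    """Average ranks (1-based) computed by explicit tie groups."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and values[order[j]] == values[order[i]]:
            j += 1
        avg = (i + 1 + j) / 2.0
        for k in range(i, j):
            ranks[order[k]] = avg
        i = j
    return ranks
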