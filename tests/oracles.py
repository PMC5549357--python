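"""Independent brute-force oracles used to validate the implementation.

Everything here is written for clarity, not speed: explicit loops over
definitions, so the oracle shares no code path with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def rie_bruteforce(active_ranks, n_total, alpha):
    """RIE straight from the sum definition, python floats only."""
    n = len(active_ranks)
    num = sum(math.exp(-alpha * r / n_total) for r in active_ranks)
    denom = (n / n_total) * (1 - math.exp(-alpha)) / (math.exp(alpha / n_total) - 1)
    return num / denom


def bedroc_bruteforce(active_ranks, n_total, alpha):
    """BEDROC via RIE evaluated at the explicit best/worst placements."""
    n = len(active_ranks)
    rie = rie_bruteforce(active_ranks, n_total, alpha)
    rie_best = rie_bruteforce(list(range(1, n + 1)), n_total, alpha)
    rie_worst = rie_bruteforce(list(range(n_total - n + 1, n_total + 1)), n_total, alpha)
    return (rie - rie_worst) / (rie_best - rie_worst)


def auac_bruteforce(active_ranks, n_total):
    """Trapezoid over the step accumulation curve, point by point."""
    n = len(active_ranks)
    actives = set(active_ranks)
    xs = [0.0]
    ys = [0.0]
    found = 0
    for i in range(1, n_total + 1):
        if i in actives:
            found += 1
        xs.append(i / n_total)
        ys.append(found / n)
    area = 0.0
    for i in range(1, len(xs)):
        area += (xs[i] - xs[i - 1]) * (ys[i] + ys[i - 1]) / 2
    return area


def roc_bruteforce(active_ranks, n_total):
    n = len(active_ranks)
    actives = set(active_ranks)
    tpr = [0.0]
    fpr = [0.0]
    tp = fp = 0
    for i in range(1, n_total + 1):
        if i in actives:
            tp += 1
        else:
            fp += 1
        tpr.append(tp / n)
        fpr.append(fp / (n_total - n))
    area = 0.0
    for i in range(1, len(tpr)):
        area += (fpr[i] - fpr[i - 1]) * (tpr[i] + tpr[i - 1]) / 2
    return area


def cutoff_curve_bruteforce(ordered_genes, consen_scores, reference):
    """I_i per rank by re-walking the table with explicit set intersections."""
    ref = set(reference)
    out = []
    for i in range(1, len(ordered_genes) + 1):
        top = set(ordered_genes[:i])
        tp = len(top & ref)
        fp = i - tp
        out.append(tp / (fp + 1) * consen_scores[i - 1])
    return out


def k_clique_communities_bruteforce(graph, k):
    """Direct clique percolation: enumerate every k-clique, chain cliques
    sharing k-1 nodes, return node unions of the chained components."""
    nodes = sorted(graph.nodes, key=str)
    adj = {u: set(graph[u]) for u in nodes}
    cliques = []
    for combo in itertools.combinations(nodes, k):
        if all(v in adj[u] for u, v in itertools.combinations(combo, 2)):
            cliques.append(frozenset(combo))
    if not cliques:
        return []
    parent = list(range(len(cliques)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in itertools.combinations(range(len(cliques)), 2):
        if len(cliques[i] & cliques[j]) >= k - 1:
            parent[find(i)] = find(j)
    groups = {}
    for i, cl in enumerate(cliques):
        groups.setdefault(find(i), set()).update(cl)
    return sorted(
        (frozenset(g) for g in groups.values()),
        key=lambda c: (-len(c), sorted(map(str, c))),
    )


def largest_component_bruteforce(graph, subset):
    """Largest connected component of the induced subgraph, by flood fill."""
    subset = set(subset)
    adj = {u: set(graph[u]) & subset for u in subset}
    seen = set()
    best = 0
    for start in subset:
        if start in seen:
            continue
        stack = [start]
        comp = set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(adj[u] - comp)
        seen |= comp
        best = max(best, len(comp))
    return best


def signed_rank_pvalue_bruteforce(diffs):
    """Exact two-sided signed-rank p by enumerating all sign assignments.

    Requires nonzero differences with no tied magnitudes.
    """
    d = [x for x in diffs if x != 0]
    mags = sorted(abs(x) for x in d)
    assert len(set(mags)) == len(mags), "oracle needs untied magnitudes"
    ranks = {m: i + 1 for i, m in enumerate(mags)}
    w_plus = sum(ranks[abs(x)] for x in d if x > 0)
    n = len(d)
    total = sum(ranks.values())
    w_obs = min(w_plus, total - w_plus)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(ranks[abs(x)] for x, s in zip(d, signs) if s)
        if min(w, total - w) <= w_obs:
            count += 1
    return count / 2**n
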