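"""Community-weighted pathway scoring and subnetwork significance.

Communities detected on the interaction network are linked to pathways by
hypergeometric over-representation (BH-adjusted).  Each linked pathway m
is then scored three ways:

* ``PathRankScore_m`` — the mean, over its linked communities, of the
  community's average consensus rank (lower = earlier in the ranking);
* ``PathGeneScore_m`` — sqrt(<ConsenScore>_m * n_m / N_m), where N_m is
  the pathway size and n_m how many of its genes sit in the network;
* ``PathScore_m`` — geometric mean of PathGeneScore and the normalized
  rank term (P_max + 1 - P_m)/(P_max + 1), so that pathways linked to
  early-ranked communities and densely covered by well-scored genes rise
  to the top.

Monte-Carlo routines assess whether a gene list is unusually connected in
a reference network (largest linked component) and whether two gene sets
overlap more than random draws from the universe would.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse import csgraph
from statsmodels.stats.multitest import multipletests

from .consensus import ConsensusTable
from .network import CommunityPartition, ConfidenceNetwork

__all__ = [
    "overrepresentation",
    "CommunityPathwayMap",
    "community_pathway_map",
    "pathway_scores",
    "path_rank_score",
    "path_gene_score",
    "normalized_rank_term",
    "path_score",
    "component_significance",
    "overlap_significance",
]


def overrepresentation(genes, universe, collection: dict[str, set]) -> pd.DataFrame:
    """Hypergeometric upper-tail ORA of ``genes`` against each set, BH-adjusted.

    Sets are intersected with the universe first; ``genes`` must be a
    subset of the universe.
    """
    query = set(genes)
    uni = set(universe)
    if not query:
        raise ValueError("empty query gene set")
    if not query <= uni:
        raise ValueError("query genes must be contained in the universe")
    N = len(uni)
    n = len(query)
    rows = []
    for name in sorted(collection):
        members = set(collection[name]) & uni
        K = len(members)
        k = len(members & query)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"pathway": name, "overlap": k, "set_size": K, "pvalue": min(p, 1.0)})
    df = pd.DataFrame(rows).set_index("pathway")
    df["qvalue"] = multipletests(df["pvalue"], method="fdr_bh")[1]
    return df


@dataclass
class CommunityPathwayMap:
    """Bipartite links between community ids (1-based) and pathway names."""

    links: set[tuple[int, str]]
    q_threshold: float

    def pathways_of(self, community: int) -> set[str]:
        return {m for k, m in self.links if k == community}

    def communities_of(self, pathway: str) -> list[int]:
        return sorted(k for k, m in self.links if m == pathway)

    def pathways(self) -> list[str]:
        return sorted({m for _, m in self.links})

    def __len__(self) -> int:
        return len(self.links)


def community_pathway_map(
    partition: CommunityPartition,
    collection: dict[str, set],
    universe,
    q_threshold: float = 0.05,
) -> CommunityPathwayMap:
    """Link community k to pathway m when the community's ORA q < threshold."""
    uni = set(universe)
    links: set[tuple[int, str]] = set()
    for i, comm in enumerate(partition.communities, start=1):
        query = set(comm) & uni
        if not query:
            continue
        ora = overrepresentation(query, uni, collection)
        for name, row in ora.iterrows():
            if row["qvalue"] < q_threshold:
                links.add((i, name))
    return CommunityPathwayMap(links=links, q_threshold=q_threshold)


# -- scoring primitives ------------------------------------------------------

def path_rank_score(community_mean_ranks) -> float:
    """Mean of the linked communities' average consensus ranks."""
    ranks = np.asarray(list(community_mean_ranks), dtype=float)
    if len(ranks) == 0:
        raise ValueError("pathway linked to no community")
    return float(ranks.mean())


def path_gene_score(mean_consen_score: float, n_in_network: int, pathway_size: int) -> float:
    if pathway_size <= 0:
        raise ValueError("pathway size must be positive")
    return float(np.sqrt(mean_consen_score * n_in_network / pathway_size))


def normalized_rank_term(p: float, p_max: float) -> float:
    """(P_max + 1 - P)/(P_max + 1): maps the best rank score near 1, the worst above 0."""
    return (p_max + 1.0 - p) / (p_max + 1.0)


def path_score(gene_score: float, rank_score: float, p_max: float) -> float:
    """Geometric mean of PathGeneScore and the normalized PathRankScore."""
    return float(np.sqrt(gene_score * normalized_rank_term(rank_score, p_max)))


def pathway_scores(
    cmap: CommunityPathwayMap,
    profiles: pd.DataFrame,
    consensus: ConsensusTable,
    net: ConfidenceNetwork,
    collection: dict[str, set],
) -> pd.DataFrame:
    """Score every linked pathway; rows sorted by PathScore descending.

    Pathways with no gene in the consensus table have an undefined
    PathGeneScore and are kept with NaN scores at the bottom, excluded
    from the ranking proper.
    """
    if len(cmap) == 0:
        raise ValueError("empty community-pathway map")
    net_nodes = net.nodes
    rows = []
    for name in cmap.pathways():
        comms = cmap.communities_of(name)
        prs = path_rank_score(profiles.loc[comms, "mean_rank"])
        members = set(collection[name])
        in_consensus = [g for g in sorted(members) if g in consensus.df.index]
        n_m = len(members & net_nodes)
        if in_consensus:
            mean_cs = float(consensus.df.loc[in_consensus, "consen_score"].mean())
            pgs = path_gene_score(mean_cs, n_m, len(members))
        else:
            mean_cs, pgs = float("nan"), float("nan")
        rows.append(
            {
                "pathway": name,
                "communities": ",".join(str(c) for c in comms),
                "n_communities": len(comms),
                "path_rank_score": prs,
                "pathway_size": len(members),
                "n_in_network": n_m,
                "mean_consen_score": mean_cs,
                "path_gene_score": pgs,
            }
        )
    df = pd.DataFrame(rows).set_index("pathway")
    p_max = float(df["path_rank_score"].max())
    df["norm_rank_term"] = normalized_rank_term(df["path_rank_score"], p_max)
    df["path_score"] = np.sqrt(df["path_gene_score"] * df["norm_rank_term"])
    return df.sort_values("path_score", ascending=False, na_position="last", kind="mergesort")


# -- Monte-Carlo significance ------------------------------------------------

@dataclass
class ComponentSignificance:
    observed_size: int
    n_in_network: int
    allow_missing: int
    pvalue: float
    pvalue_randomized: float
    n_mc: int


def _largest_linked_component(
    adj: sparse.csr_matrix,
    neighbors: list[np.ndarray],
    subset: np.ndarray,
    d: int,
) -> int:
    """Largest group of subset nodes linked by paths of <= d+1 edges whose
    intermediate nodes all lie outside the subset (d = allowed missing genes)."""
    if d == 0:
        sub = adj[subset][:, subset]
        _, labels = csgraph.connected_components(sub, directed=False)
        return int(np.bincount(labels).max())
    n = adj.shape[0]
    in_subset = np.zeros(n, dtype=bool)
    in_subset[subset] = True
    pos = {node: i for i, node in enumerate(subset)}
    link = sparse.lil_matrix((len(subset), len(subset)), dtype=np.int8)
    for i, s in enumerate(subset):
        # BFS through non-subset intermediates, depth <= d+1
        dist = {s: 0}
        frontier = [s]
        for depth in range(1, d + 2):
            nxt = []
            for u in frontier:
                for v in neighbors[u]:
                    if v in dist:
                        continue
                    dist[v] = depth
                    if in_subset[v]:
                        link[i, pos[v]] = 1  # reached another input node
                    else:
                        nxt.append(v)
            frontier = nxt
        link[i, i] = 1
    _, labels = csgraph.connected_components(link.tocsr(), directed=False)
    return int(np.bincount(labels).max())


def component_significance(
    genes,
    reference_net,
    allow_missing: int = 0,
    n_mc: int = 1000,
    seed: int = 0,
) -> ComponentSignificance:
    """Size of the largest linked component of ``genes`` in the network, with a
    Monte-Carlo p-value against equally sized random gene draws.

    ``allow_missing`` d in {0, 1, 2}: with d > 0 two input genes also count
    as linked when at most d non-input genes bridge them.  The conservative
    p is (1 + #{sim >= obs})/(n_mc + 1); the randomized variant breaks ties
    uniformly and is exactly Uniform(0,1) under the null.
    """
    if allow_missing not in (0, 1, 2):
        raise ValueError("allow_missing must be 0, 1 or 2")
    if n_mc < 100:
        raise ValueError("n_mc must be >= 100")
    graph = reference_net.graph if isinstance(reference_net, ConfidenceNetwork) else reference_net
    nodes = sorted(graph.nodes, key=str)
    idx = {n: i for i, n in enumerate(nodes)}
    present = sorted(set(genes) & set(nodes), key=str)
    if not present:
        raise ValueError("no input gene present in the reference network")
    adj = nx.to_scipy_sparse_array(graph, nodelist=nodes, format="csr")
    adj = sparse.csr_matrix(adj)
    neighbors = [adj.indices[adj.indptr[i]: adj.indptr[i + 1]] for i in range(len(nodes))]

    subset = np.array([idx[g] for g in present])
    obs = _largest_linked_component(adj, neighbors, subset, allow_missing)

    rng = np.random.default_rng(seed)
    m = len(subset)
    sims = np.empty(n_mc, dtype=int)
    for r in range(n_mc):
        draw = rng.choice(len(nodes), size=m, replace=False)
        sims[r] = _largest_linked_component(adj, neighbors, np.sort(draw), allow_missing)
    ge = int(np.sum(sims >= obs))
    gt = int(np.sum(sims > obs))
    p = (1 + ge) / (n_mc + 1)
    p_rand = (gt + rng.uniform() * (1 + ge - gt)) / (n_mc + 1)
    return ComponentSignificance(
        observed_size=int(obs),
        n_in_network=m,
        allow_missing=allow_missing,
        pvalue=float(p),
        pvalue_randomized=float(p_rand),
        n_mc=n_mc,
    )


@dataclass
class OverlapSignificance:
    overlap: int
    expected: float
    pvalue: float
    pvalue_randomized: float
    pvalue_hypergeom: float
    n_perm: int


def overlap_significance(
    set_a, set_b, universe, n_perm: int = 999, seed: int = 0
) -> OverlapSignificance:
    """Is |A ∩ B| larger than for a uniformly redrawn A of the same size?

    The permutation p redraws A from the universe ``n_perm`` times; the
    exact hypergeometric upper tail is reported alongside.
    """
    uni = sorted(set(universe))
    if not uni:
        raise ValueError("empty universe")
    a = set(set_a)
    b = set(set_b)
    if not (a <= set(uni) and b <= set(uni)):
        raise ValueError("both sets must be contained in the universe")
    obs = len(a & b)
    N, nb, na = len(uni), len(b), len(a)
    rng = np.random.default_rng(seed)
    uni_arr = np.array(uni)
    is_b = np.isin(uni_arr, sorted(b))
    sims = np.empty(n_perm, dtype=int)
    for r in range(n_perm):
        draw = rng.choice(N, size=na, replace=False)
        sims[r] = int(is_b[draw].sum())
    ge = int(np.sum(sims >= obs))
    gt = int(np.sum(sims > obs))
    p = (1 + ge) / (n_perm + 1)
    p_rand = (gt + rng.uniform() * (1 + ge - gt)) / (n_perm + 1)
    p_hyper = float(stats.hypergeom.sf(obs - 1, N, nb, na))
    return OverlapSignificance(
        overlap=obs,
        expected=na * nb / N,
        pvalue=float(p),
        pvalue_randomized=float(p_rand),
        pvalue_hypergeom=p_hyper,
        n_perm=n_perm,
    )
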