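"""Confidence-filtered interaction network and clique-percolation communities.

Edges carry a functional-association confidence in [0, 1] (STRING-dialect
integer scores 0-1000 are divided by 1000).  After filtering at a
confidence cutoff (default 0.9, inclusive), overlapping communities are
found by the clique percolation method (CPM): two k-cliques are adjacent
when they share k-1 nodes, and a community is the node union of a
connected component of that clique adjacency.  The clique size k is chosen
by minimizing the balance index

    S^k = |mean(N_g^k) - median(N_g^k)| / N_c^k

over the community gene-count distribution (N_g) and community count (N_c).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import k_clique_communities as _nx_cpm

from .consensus import ConsensusTable

__all__ = [
    "ConfidenceNetwork",
    "CommunityPartition",
    "build_network",
    "find_k_clique_communities",
    "scan_k",
    "community_profiles",
    "degree_association",
]


@dataclass
class ConfidenceNetwork:
    graph: nx.Graph
    cutoff: float

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree_of(self, node: str) -> int:
        return self.graph.degree[node]


@dataclass
class CommunityPartition:
    k: int
    communities: list[frozenset]
    graph: nx.Graph = field(repr=False)

    def __post_init__(self) -> None:
        # deterministic ordering: size desc, then lexicographic member tuple
        self.communities = sorted(
            (frozenset(c) for c in self.communities),
            key=lambda c: (-len(c), sorted(map(str, c))),
        )

    def __len__(self) -> int:
        return len(self.communities)

    def sizes(self) -> np.ndarray:
        return np.array([len(c) for c in self.communities])

    def membership(self) -> dict[str, list[int]]:
        """Gene -> 1-based ids of every community it joins (overlaps allowed)."""
        out: dict[str, list[int]] = {}
        for i, comm in enumerate(self.communities, start=1):
            for g in comm:
                out.setdefault(g, []).append(i)
        return out

    def multi_membership_genes(self) -> set[str]:
        return {g for g, ids in self.membership().items() if len(ids) > 1}

    def s_index(self) -> float:
        sizes = self.sizes()
        if len(sizes) == 0:
            return float("nan")
        return float(abs(sizes.mean() - np.median(sizes)) / len(sizes))


def build_network(edges: pd.DataFrame, cutoff: float = 0.9) -> ConfidenceNetwork:
    """Filter a STRING-dialect edge table at the confidence cutoff (inclusive).

    ``edges`` needs columns (protein1, protein2, combined_score); scores
    above 1 are read as STRING integers and divided by 1000.  Self-loops
    are dropped and duplicate edges deduplicated keeping the maximum
    confidence.  Nodes left without any retained edge do not appear.
    """
    required = {"protein1", "protein2", "combined_score"}
    if not required.issubset(edges.columns):
        raise ValueError(f"edge table must have columns {sorted(required)}")
    conf = pd.to_numeric(edges["combined_score"], errors="coerce")
    if conf.isna().any():
        bad = int(conf.isna().idxmax())
        raise ValueError(f"malformed combined_score at row {bad}")
    conf = conf.astype(float)
    if (conf > 1).any():
        conf = conf / 1000.0
    if ((conf < 0) | (conf > 1)).any():
        raise ValueError("confidence outside [0, 1] after scaling")

    g = nx.Graph()
    a = edges["protein1"].astype(str).to_numpy()
    b = edges["protein2"].astype(str).to_numpy()
    c = conf.to_numpy()
    keep = c >= cutoff
    for u, v, w in zip(a[keep], b[keep], c[keep]):
        if u == v:
            continue
        if g.has_edge(u, v):
            if w > g[u][v]["confidence"]:
                g[u][v]["confidence"] = w
        else:
            g.add_edge(u, v, confidence=w)
    if g.number_of_edges() == 0:
        warnings.warn("no edge passes the confidence cutoff", stacklevel=2)
    return ConfidenceNetwork(graph=g, cutoff=cutoff)


def find_k_clique_communities(net: ConfidenceNetwork, k: int) -> CommunityPartition:
    """CPM communities at clique size k (maximal-clique percolation)."""
    if k < 3:
        raise ValueError("clique percolation requires k >= 3")
    comms = [frozenset(c) for c in _nx_cpm(net.graph, k)]
    return CommunityPartition(k=k, communities=comms, graph=net.graph)


@dataclass
class KScanResult:
    table: pd.DataFrame           # k, n_communities, s_index, sizes
    partitions: dict[int, CommunityPartition]
    selected_k: int

    def partition(self, k: int | None = None) -> CommunityPartition:
        return self.partitions[self.selected_k if k is None else k]


def scan_k(net: ConfidenceNetwork, k_range, k_override: int | None = None) -> KScanResult:
    """Scan clique sizes, compute S^k and pick argmin (ties -> smaller k).

    ``k_override`` forces the selected k (it must yield communities); the
    automatic argmin rule is a balance heuristic and the final choice may
    legitimately use outside judgment.
    """
    rows = []
    partitions: dict[int, CommunityPartition] = {}
    for k in sorted(k_range):
        part = find_k_clique_communities(net, k)
        if len(part) == 0:
            continue
        partitions[k] = part
        rows.append(
            {
                "k": k,
                "n_communities": len(part),
                "s_index": part.s_index(),
                "sizes": tuple(int(s) for s in part.sizes()),
            }
        )
    if not rows:
        raise ValueError("no k in the range yields any community")
    table = pd.DataFrame(rows)
    if k_override is not None:
        if k_override not in partitions:
            raise ValueError(f"k_override={k_override} yields no community")
        selected = k_override
    else:
        best = table["s_index"].min()
        selected = int(table.loc[table["s_index"] == best, "k"].min())
    return KScanResult(table=table, partitions=partitions, selected_k=selected)


def community_profiles(
    partition: CommunityPartition,
    consensus: ConsensusTable,
    reference=None,
) -> pd.DataFrame:
    """Per-community summary: mean consensus score/rank, mean degree, reference count.

    Genes in several communities contribute to each of them; community
    genes missing from the consensus table are excluded from the score and
    rank means but still count toward size and degree.
    """
    if len(partition) == 0:
        raise ValueError("empty community partition")
    ref = set()
    if reference is not None:
        ref = reference.ids() if hasattr(reference, "ids") else set(reference)
    deg = partition.graph.degree
    rows = []
    for i, comm in enumerate(partition.communities, start=1):
        genes = sorted(comm)
        in_table = [g for g in genes if g in consensus.df.index]
        cs = consensus.df.loc[in_table, "consen_score"]
        rk = consensus.df.loc[in_table, "rank"]
        rows.append(
            {
                "community": i,
                "size": len(genes),
                "n_scored": len(in_table),
                "mean_consen_score": float(cs.mean()) if in_table else float("nan"),
                "mean_rank": float(rk.mean()) if in_table else float("nan"),
                "mean_degree": float(np.mean([deg[g] for g in genes])),
                "n_pathogenic": int(sum(g in ref for g in genes)),
                "genes": ",".join(genes),
            }
        )
    return pd.DataFrame(rows).set_index("community")


@dataclass
class DegreeAssociation:
    mean_reference: float
    mean_other: float
    pvalue: float
    n_reference: int
    n_other: int


def degree_association(
    net: ConfidenceNetwork, reference, n_perm: int = 1000, seed: int = 0
) -> DegreeAssociation:
    """One-sided permutation test: do reference genes have higher degree?"""
    ref = reference.ids() if hasattr(reference, "ids") else set(reference)
    nodes = sorted(net.nodes, key=str)
    is_ref = np.array([n in ref for n in nodes])
    n_ref = int(is_ref.sum())
    if n_ref == 0:
        raise ValueError("no reference gene in the network")
    if n_ref == len(nodes):
        raise ValueError("reference covers every network node")
    degs = np.array([net.graph.degree[n] for n in nodes], dtype=float)
    obs = degs[is_ref].mean() - degs[~is_ref].mean()
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(nodes))[:n_ref]
        mask = np.zeros(len(nodes), dtype=bool)
        mask[perm] = True
        if degs[mask].mean() - degs[~mask].mean() >= obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return DegreeAssociation(
        mean_reference=float(degs[is_ref].mean()),
        mean_other=float(degs[~is_ref].mean()),
        pvalue=float(p),
        n_reference=n_ref,
        n_other=len(nodes) - n_ref,
    )
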