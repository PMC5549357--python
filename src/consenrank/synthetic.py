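"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes
rather than any particular biological dataset:

* ranked lists — each gene carries a latent quality (planted positives
  ~ Beta(a, 1), so larger ``a`` pushes them toward 1; the rest ~ U(0, 1));
  each source observes the quality plus Gaussian noise for the genes its
  coverage Bernoulli included, and ranks what it sees;
* interaction network — consecutive planted cliques of size s sharing o
  nodes, intra-clique confidences drawn above the filtering threshold,
  plus Bernoulli background edges scored below it;
* differential-expression studies — a designated DE pool with a true
  direction per gene; each study includes a pool gene with fixed
  probability and flips its sign with a small probability, creating
  ambiguous genes;
* pathway sets — optionally planted against a community partition: set m
  holds a stated fraction of community m's genes plus random fillers.

All randomness flows from ``SimConfig.seed`` through per-generator
``SeedSequence`` children, so the same config reproduces every output
bit-for-bit while the generators stay independent of one another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimConfig
from .consensus import RankedGeneList, normalize_ranked_list

__all__ = [
    "simulate_method_lists",
    "simulate_network",
    "simulate_microarray_studies",
    "simulate_pathway_collection",
]

# fixed stream tags keep the four generators statistically independent
_STREAM_LISTS = 1
_STREAM_NETWORK = 2
_STREAM_STUDIES = 3
_STREAM_PATHWAYS = 4


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _latent_quality(config: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n = config.n_genes
    is_pos = np.zeros(n, dtype=bool)
    pos_idx = rng.choice(n, size=config.n_positives, replace=False)
    is_pos[pos_idx] = True
    quality = rng.uniform(0.0, 1.0, size=n)
    if math.isinf(config.signal_a):
        quality[is_pos] = 1.0
    else:
        quality[is_pos] = rng.beta(config.signal_a, 1.0, size=config.n_positives)
    return quality, is_pos


def simulate_method_lists(config: SimConfig) -> tuple[list[RankedGeneList], set[str]]:
    """J ranked lists with planted positives enriched toward the top.

    Returns the normalized lists and the planted positive gene set.
    Inclusion is an independent Bernoulli per gene and method
    (coverage_pos for positives, coverage_neg for the rest); within a list
    genes are ordered by quality + N(0, noise_sd), ties broken by gene id.
    """
    config.validate()
    rng = _rng(config, _STREAM_LISTS)
    genes = np.array(config.gene_universe())
    quality, is_pos = _latent_quality(config, rng)
    p_include = np.where(is_pos, config.coverage_pos, config.coverage_neg)

    lists = []
    for j in range(config.n_methods):
        include = rng.uniform(size=config.n_genes) < p_include
        if not include.any():
            include[rng.integers(config.n_genes)] = True  # never emit an empty list
        observed = quality[include]
        if config.noise_sd > 0:
            observed = observed + rng.normal(0.0, config.noise_sd, size=observed.size)
        sub_genes = genes[include]
        order = np.lexsort((sub_genes, -observed))
        lists.append(
            normalize_ranked_list(f"method_{j + 1:02d}", list(sub_genes[order]), mode="rank")
        )
    positives = set(genes[is_pos])
    return lists, positives


def simulate_network(config: SimConfig) -> tuple[pd.DataFrame, list[set]]:
    """STRING-dialect edge table with planted clique communities.

    Planted communities are cliques of ``community_size`` genes,
    consecutive communities sharing ``community_overlap`` nodes; their
    edges draw integer confidences from the above-threshold range.
    Background edges appear with ``background_edge_prob`` between any
    other node pair (planted + extra pool) and score below the threshold.
    """
    config.validate()
    rng = _rng(config, _STREAM_NETWORK)
    s, o = config.community_size, config.community_overlap
    n_planted = config.n_communities * s - (config.n_communities - 1) * o
    n_nodes = n_planted + config.n_network_extra
    if n_nodes > config.n_genes:
        raise ValueError("gene universe too small for the requested network")
    genes = np.array(config.gene_universe())
    chosen = genes[rng.choice(config.n_genes, size=n_nodes, replace=False)]

    communities = []
    planted_pairs = set()
    for c in range(config.n_communities):
        start = c * (s - o)
        members = chosen[start: start + s]
        communities.append(set(members))
        for i in range(s):
            for j in range(i + 1, s):
                u, v = sorted((members[i], members[j]))
                planted_pairs.add((u, v))

    rows = []
    for u, v in sorted(planted_pairs):
        score = int(rng.integers(config.intra_score_low, config.intra_score_high + 1))
        rows.append((u, v, score))

    if config.background_edge_prob > 0:
        nodes_sorted = np.sort(chosen)
        n = len(nodes_sorted)
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.uniform(size=len(iu)) < config.background_edge_prob
        for a, b in zip(nodes_sorted[iu[mask]], nodes_sorted[ju[mask]]):
            u, v = sorted((a, b))
            if (u, v) in planted_pairs:
                continue
            score = int(
                rng.integers(config.background_score_low, config.background_score_high + 1)
            )
            rows.append((u, v, score))

    edges = pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])
    return edges, communities


def simulate_microarray_studies(
    config: SimConfig,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Per-study DE tables plus the planted truth (pool genes, true signs)."""
    config.validate()
    rng = _rng(config, _STREAM_STUDIES)
    genes = np.array(config.gene_universe())
    pool = np.sort(genes[rng.choice(config.n_genes, size=config.n_de_genes, replace=False)])
    true_dir = rng.choice(["up", "down"], size=config.n_de_genes)

    studies: dict[str, pd.DataFrame] = {}
    for j in range(config.n_studies):
        include = rng.uniform(size=config.n_de_genes) < config.study_inclusion_prob
        if not include.any():
            include[rng.integers(config.n_de_genes)] = True
        sub = pool[include]
        direction = true_dir[include].copy()
        flip = rng.uniform(size=len(sub)) < config.sign_flip_prob
        direction[flip] = np.where(direction[flip] == "up", "down", "up")
        adj_p = rng.uniform(1e-8, 0.05, size=len(sub))
        studies[f"A{j + 1}"] = pd.DataFrame(
            {"gene_id": sub, "adjusted_p": adj_p, "direction": direction}
        )
    truth = {
        "de_pool": list(pool),
        "true_direction": dict(zip(pool, true_dir)),
    }
    return studies, truth


def simulate_pathway_collection(
    config: SimConfig,
    communities: list[set] | None = None,
    planted_fraction: float = 0.8,
    n_filler: int = 5,
    n_random_sets: int = 0,
    random_set_size: int = 15,
) -> dict[str, set]:
    """Named gene sets, optionally planted against a community list.

    When ``communities`` is given, set m contains ``planted_fraction`` of
    community m's genes plus ``n_filler`` random universe genes; extra
    purely random sets can be appended.
    """
    config.validate()
    if not 0.0 <= planted_fraction <= 1.0:
        raise ValueError("planted_fraction must lie in [0, 1]")
    rng = _rng(config, _STREAM_PATHWAYS)
    genes = np.array(config.gene_universe())
    collection: dict[str, set] = {}
    if communities is not None:
        for m, comm in enumerate(communities, start=1):
            members = np.sort(np.array(sorted(comm)))
            n_take = int(round(planted_fraction * len(members)))
            taken = set(members[rng.choice(len(members), size=n_take, replace=False)])
            if n_filler > 0:
                fillers = set(genes[rng.choice(config.n_genes, size=n_filler, replace=False)])
                taken |= fillers
            if taken:
                collection[f"pathway_{m:02d}"] = taken
    for m in range(n_random_sets):
        members = set(genes[rng.choice(config.n_genes, size=random_set_size, replace=False)])
        collection[f"random_set_{m + 1:02d}"] = members
    return collection
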