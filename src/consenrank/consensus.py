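"""Rank aggregation across gene-prioritization sources.

Each source contributes an ordered gene list.  Scores are first mapped to a
common [0, 1] scale (``GeneN``), then fused per gene through the geometric
mean of (i) the average normalized score over the sources that report the
gene and (ii) the fraction of sources reporting it,

    Gene_i = sqrt( (n_i - 1)/(J - 1) * mean_j GeneN_ij ),

with an arithmetic-mean tiebreak for genes reported by a single source.
Sorting by (Gene_i, tiebreak) and renormalizing the resulting rank yields
the final consensus score ``ConsenScore_i = (N - rank_i + 1)/N``.

A ranking-quality index I_i = TP_i/(FP_i + 1) * ConsenScore_i evaluated
along the sorted table gives a data-driven cutoff for how many genes to
retain: its argmax balances true versus false positives weighted by how
high the gene still scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RankedGeneList",
    "ConsensusTable",
    "CutoffCurve",
    "normalize_ranked_list",
    "consensus_scores",
    "rational_cutoff",
]


@dataclass
class RankedGeneList:
    """One source's ordered genes with normalized scores in [0, 1]."""

    method_id: str
    gene_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.gene_ids) == 0:
            raise ValueError(f"method {self.method_id!r}: empty ranked list")
        if len(self.gene_ids) != len(self.scores):
            raise ValueError("gene_ids and scores length mismatch")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"method {self.method_id!r}: duplicate gene ids")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError(f"method {self.method_id!r}: scores increase with rank")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class ConsensusTable:
    """Aggregated ranking; ``df`` is indexed by gene_id, sorted by rank."""

    df: pd.DataFrame
    n_methods: int

    @property
    def n_genes(self) -> int:
        return len(self.df)

    def ranks_of(self, genes) -> pd.Series:
        """Consensus ranks of the requested genes (found genes only)."""
        found = [g for g in genes if g in self.df.index]
        return self.df.loc[found, "rank"]

    def top(self, n: int) -> pd.DataFrame:
        return self.df.iloc[:n]


@dataclass
class CutoffCurve:
    df: pd.DataFrame          # rank, gene_id, tp, fp, index, index_rate
    selected_rank: int
    selected_index: float
    variant: str = "count"


def normalize_ranked_list(
    method_id: str,
    gene_ids: list[str],
    raw_scores=None,
    mode: str = "rank",
) -> RankedGeneList:
    """Map one source's ranked list to the common [0, 1] scale.

    ``rank`` mode assigns GeneN = (M - r + 1)/M to the gene at 1-based
    position r; ``score`` mode rescales the supplied raw scores min-max
    (larger = better).  The input ordering (best first) is preserved.
    """
    M = len(gene_ids)
    if M == 0:
        raise ValueError("cannot normalize an empty list")
    if mode == "rank":
        scores = (M - np.arange(1, M + 1) + 1) / M
    elif mode == "score":
        if raw_scores is None:
            raise ValueError("score mode requires raw scores")
        raw = np.asarray(raw_scores, dtype=float)
        if not np.all(np.isfinite(raw)):
            raise ValueError("score mode requires finite raw scores")
        span = raw.max() - raw.min()
        if span == 0:
            warnings.warn(
                f"method {method_id!r}: constant raw scores, all GeneN set to 1",
                stacklevel=2,
            )
            scores = np.ones(M)
        else:
            scores = (raw - raw.min()) / span
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return RankedGeneList(method_id=method_id, gene_ids=list(gene_ids), scores=scores)


def consensus_scores(lists: list[RankedGeneList], n_methods: int | None = None) -> ConsensusTable:
    """Fuse the per-source lists into the consensus table.

    ``n_methods`` (J) defaults to the number of supplied lists; it may be
    larger when some sources returned nothing.  A gene reported by a single
    source gets Gene_i = 0 and competes through the tiebreak only.
    """
    J = n_methods if n_methods is not None else len(lists)
    if J < 2:
        raise ValueError("consensus requires at least two methods")
    if len(lists) == 0:
        raise ValueError("no ranked lists supplied")

    frames = [
        pd.DataFrame({"gene_id": rl.gene_ids, "gene_n": rl.scores})
        for rl in lists
    ]
    long = pd.concat(frames, ignore_index=True)
    grouped = long.groupby("gene_id")["gene_n"].agg(["count", "mean"])
    n_i = grouped["count"].to_numpy()
    if n_i.max() > J:
        raise ValueError(
            f"a gene appears in {n_i.max()} lists but only J={J} methods declared"
        )
    mean_norm = grouped["mean"].to_numpy()
    frac = (n_i - 1) / (J - 1)
    gene_score = np.sqrt(frac * mean_norm)
    tiebreak = (frac + mean_norm) / 2.0

    table = pd.DataFrame(
        {
            "n_methods": n_i,
            "mean_norm": mean_norm,
            "gene_score": gene_score,
            "tiebreak": tiebreak,
        },
        index=grouped.index,
    )
    # deterministic order: score desc, tiebreak desc, gene_id asc
    table = table.sort_index(kind="mergesort").sort_values(
        by=["gene_score", "tiebreak"], ascending=False, kind="mergesort"
    )
    N = len(table)
    pos = np.arange(1, N + 1)
    gs = table["gene_score"].to_numpy()
    tb = table["tiebreak"].to_numpy()
    new_block = np.ones(N, dtype=bool)
    new_block[1:] = (gs[1:] != gs[:-1]) | (tb[1:] != tb[:-1])
    # competition ranking: ties share the first (minimum) position
    rank = pos[new_block][np.cumsum(new_block) - 1]
    table["rank"] = rank
    table["consen_score"] = (N - rank + 1) / N
    return ConsensusTable(df=table, n_methods=J)


def rational_cutoff(
    table: ConsensusTable,
    reference,
    variant: str = "count",
) -> CutoffCurve:
    """Walk the sorted consensus table and locate the argmax of I_i.

    The ``count`` variant uses raw TP/FP counts, the ``rate`` variant uses
    TPR/(FPR + 1); both columns are always reported, ``variant`` only picks
    which one defines the selected cutoff rank.
    """
    if variant not in {"count", "rate"}:
        raise ValueError(f"unknown cutoff variant {variant!r}")
    ref = set(reference.members) if hasattr(reference, "members") else set(reference)
    if not ref:
        raise ValueError("reference gene set is empty")

    df = table.df
    N = len(df)
    hits = df.index.isin(ref).astype(int)
    n_found = int(hits.sum())
    if n_found == 0:
        warnings.warn("reference set disjoint from the consensus table", stacklevel=2)
    tp = np.cumsum(hits)
    pos = np.arange(1, N + 1)
    fp = pos - tp
    cs = df["consen_score"].to_numpy()
    index_count = tp / (fp + 1) * cs
    if n_found and n_found < N:
        tpr = tp / n_found
        fpr = fp / (N - n_found)
        index_rate = tpr / (fpr + 1) * cs
    else:
        index_rate = np.zeros(N)

    curve = pd.DataFrame(
        {
            "rank": pos,
            "gene_id": df.index.to_numpy(),
            "tp": tp,
            "fp": fp,
            "index": index_count,
            "index_rate": index_rate,
        }
    )
    chosen = index_count if variant == "count" else index_rate
    sel = int(np.argmax(chosen))  # first index on ties
    return CutoffCurve(
        df=curve,
        selected_rank=int(pos[sel]),
        selected_index=float(chosen[sel]),
        variant=variant,
    )
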