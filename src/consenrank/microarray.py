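"""Cross-study consensus of differential-expression gene lists.

Each study contributes its significant genes (adjusted p < 0.05) with a
direction of regulation.  Within a study, genes are ranked by ascending
adjusted p and rank-normalized to GeneS = (M - r + 1)/M; across studies
the vote-weighted score

    GeneAS_i = sqrt( (Narray_i - 1)/(S - 1) * mean_j GeneS_ij )

rewards genes reported by many studies with high significance.  A gene is
classified up- or down-regulated only when every reporting study agrees;
any sign conflict makes it ambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus import ConsensusTable
from .network import CommunityPartition

__all__ = [
    "StudyTable",
    "MicroarrayConsensusTable",
    "score_study_genes",
    "microarray_consensus",
    "cross_study_overlaps",
    "community_microarray_weights",
]

logger = logging.getLogger(__name__)

VALID_DIRECTIONS = {"up", "down"}


@dataclass
class StudyTable:
    study_id: str
    df: pd.DataFrame  # gene_id index; adjusted_p, direction, gene_s

    def genes(self) -> set[str]:
        return set(self.df.index)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class MicroarrayConsensusTable:
    df: pd.DataFrame  # gene_id index; n_arrays, mean_gene_s, gene_as, direction
    n_studies: int

    def gene_as_of(self, genes) -> pd.Series:
        found = [g for g in genes if g in self.df.index]
        return self.df.loc[found, "gene_as"]

    def class_counts(self) -> dict[str, int]:
        return self.df["direction"].value_counts().to_dict()


def score_study_genes(studies: dict[str, pd.DataFrame]) -> list[StudyTable]:
    """Rank each study's genes by ascending adjusted p and normalize.

    Ties in p are broken by gene_id so reruns are deterministic.  Rows
    with adjusted p outside (0, 1) or an unknown direction are rejected
    and logged.
    """
    out = []
    for study_id in sorted(studies):
        df = studies[study_id].copy()
        required = {"gene_id", "adjusted_p", "direction"}
        if not required.issubset(df.columns):
            raise ValueError(f"study {study_id!r}: need columns {sorted(required)}")
        p = pd.to_numeric(df["adjusted_p"], errors="coerce")
        bad = p.isna() | (p <= 0) | (p >= 1) | ~df["direction"].isin(VALID_DIRECTIONS)
        if bad.any():
            logger.warning(
                "study %s: rejected %d malformed rows", study_id, int(bad.sum())
            )
            df = df[~bad]
        if df.empty:
            raise ValueError(f"study {study_id!r}: no valid rows")
        if df["gene_id"].duplicated().any():
            raise ValueError(f"study {study_id!r}: duplicate gene rows")
        df = df.sort_values(["adjusted_p", "gene_id"], kind="mergesort")
        M = len(df)
        df["gene_s"] = (M - np.arange(1, M + 1) + 1) / M
        out.append(StudyTable(study_id=study_id, df=df.set_index("gene_id")))
    return out


def microarray_consensus(
    studies: list[StudyTable], s_total: int | None = None
) -> MicroarrayConsensusTable:
    """Combine scored studies into the per-gene consensus table.

    ``s_total`` (S in the score's denominator) defaults to the number of
    supplied studies.
    """
    S = s_total if s_total is not None else len(studies)
    if S < 2:
        raise ValueError("microarray consensus requires at least two studies")
    frames = [
        st.df.reset_index()[["gene_id", "gene_s", "direction"]] for st in studies
    ]
    long = pd.concat(frames, ignore_index=True)
    agg = long.groupby("gene_id").agg(
        n_arrays=("gene_s", "count"),
        mean_gene_s=("gene_s", "mean"),
        n_up=("direction", lambda d: int((d == "up").sum())),
        n_down=("direction", lambda d: int((d == "down").sum())),
    )
    gene_as = np.sqrt((agg["n_arrays"] - 1) / (S - 1) * agg["mean_gene_s"])
    direction = np.where(
        (agg["n_up"] > 0) & (agg["n_down"] > 0),
        "ambiguous",
        np.where(agg["n_up"] > 0, "up", "down"),
    )
    df = pd.DataFrame(
        {
            "n_arrays": agg["n_arrays"],
            "mean_gene_s": agg["mean_gene_s"],
            "gene_as": gene_as,
            "direction": direction,
        },
        index=agg.index,
    ).sort_values(["gene_as", "n_arrays"], ascending=False, kind="mergesort")
    return MicroarrayConsensusTable(df=df, n_studies=S)


def cross_study_overlaps(
    studies: list[StudyTable], consensus: ConsensusTable | None = None
) -> dict:
    """Pairwise/all-way gene-set intersections and per-study consensus overlap."""
    if len(studies) < 2:
        raise ValueError("need at least two studies")
    sets = {st.study_id: st.genes() for st in studies}
    ids = sorted(sets)
    pairwise = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    for i in ids:
        for j in ids:
            pairwise.loc[i, j] = len(sets[i] & sets[j])
    all_way = set.intersection(*sets.values())
    report: dict = {
        "pairwise": pairwise,
        "all_way_count": len(all_way),
        "union_count": len(set.union(*sets.values())),
    }
    if consensus is not None:
        rows = []
        cons_genes = set(consensus.df.index)
        for i in ids:
            shared = sorted(sets[i] & cons_genes)
            cs = consensus.df.loc[shared, "consen_score"]
            rows.append(
                {
                    "study": i,
                    "n_shared": len(shared),
                    "pct_of_study": 100.0 * len(shared) / len(sets[i]),
                    "mean_consen_score": float(cs.mean()) if shared else float("nan"),
                }
            )
        report["consensus_overlap"] = pd.DataFrame(rows).set_index("study")
    return report


def community_microarray_weights(
    partition: CommunityPartition, ma_table: MicroarrayConsensusTable
) -> dict[int, float]:
    """Per-community weight: sum of member GeneAS over full community size.

    Genes without microarray evidence contribute zero to the sum but stay
    in the denominator, so sparsely covered communities get small weights.
    """
    weights = {}
    for i, comm in enumerate(partition.communities, start=1):
        if len(comm) == 0:
            raise ValueError(f"community {i} is empty")
        present = ma_table.gene_as_of(sorted(comm))
        weights[i] = float(present.sum()) / len(comm)
    return weights
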