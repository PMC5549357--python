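"""Curated reference data for the preeclampsia case study.

Two literature-curated pathogenic gene sets anchor the validation:

* G1 — genes whose silencing or forced overexpression in animal models
  produces a preeclampsia-like phenotype (27 genes);
* G2 — genes with at least one variant associated with preeclampsia in a
  meta-analysis (13 genes).

Their union holds 35 unique genes (NOS3, VEGFA, TGFB1, AGTR1 and IL10
appear in both).  Genes are keyed by Entrez ID with the symbol as label.

The module also ships the published community summary (average consensus
rank per clique-percolation community at k = 9) and the community-weighted
KEGG pathway table for that study, used as desk-scale regression fixtures
for the pathway-scoring arithmetic.
"""

from __future__ import annotations

import pandas as pd

from .benchmark import ReferenceGeneSet

__all__ = [
    "G1",
    "G2",
    "pathogenic_reference",
    "COMMUNITY_SUMMARY",
    "PATHWAY_TABLE",
    "pathway_fixture_frame",
]

# symbol -> Entrez ID
G1 = {
    "ADA": "100",
    "ADORA2A": "135",
    "ADORA2B": "136",
    "AGTR1": "185",
    "APOH": "350",
    "CD73": "4907",
    "CRP": "1401",
    "ENG": "2022",
    "EDN1": "1606",
    "FLT1": "2321",
    "GADD45A": "1647",
    "HADHA": "3030",
    "HIF1A": "3091",
    "IDO1": "3620",
    "IL10": "3586",
    "IL17A": "3605",
    "IL6": "2569",
    "NOS1": "4842",
    "NOS2": "4843",
    "NOS3": "4846",
    "PGF": "5228",
    "ROS1": "6098",
    "TACR3": "6870",
    "TGFB1": "7040",
    "TNF": "7124",
    "TNFSF14": "8740",
    "VEGFA": "7422",
}

G2 = {
    "F5": "2153",
    "F2": "2147",
    "AGT": "183",
    "MTHFR": "4524",
    "NOS3": "4846",
    "ACE": "1636",
    "SERPINE1": "5054",
    "VEGFA": "7422",
    "LEPR": "3953",
    "TGFB1": "7040",
    "AGTR1": "185",
    "HLA-G": "3135",
    "IL10": "3586",
}


def pathogenic_reference(which: str = "G1,2") -> ReferenceGeneSet:
    """Pathogenic reference set keyed by Entrez ID: 'G1', 'G2' or the union 'G1,2'."""
    if which == "G1":
        members = {entrez: sym for sym, entrez in G1.items()}
    elif which == "G2":
        members = {entrez: sym for sym, entrez in G2.items()}
    elif which in ("G1,2", "G12", "union"):
        members = {entrez: sym for sym, entrez in {**G1, **G2}.items()}
    else:
        raise ValueError(f"unknown reference set {which!r}")
    return ReferenceGeneSet(name=which, members=members)


# Published per-community summary at k = 9 (community id -> statistics).
COMMUNITY_SUMMARY = pd.DataFrame(
    [
        (1, 0.989, 210.20, 10),
        (2, 0.995, 89.07, 14),
        (3, 0.987, 243.92, 12),
        (4, 0.985, 273.25, 17),
        (5, 0.987, 231.04, 26),
        (6, 0.991, 171.28, 25),
        (7, 0.983, 304.50, 12),
        (8, 0.989, 210.67, 9),
        (9, 0.989, 194.56, 9),
    ],
    columns=["community", "mean_consen_score", "mean_rank", "size"],
).set_index("community")

# Published community-weighted pathway table:
# (pathway, linked communities, PathGeneScore, printed PathRankScore, printed PathScore)
PATHWAY_TABLE = [
    ("VEGF signaling pathway", (2,), 0.422, 89.07, 0.547),
    ("mTOR signaling pathway", (2, 6), 0.445, 130.18, 0.505),
    ("Adipocytokine signaling pathway", (1, 2, 8), 0.518, 169.98, 0.479),
    ("Intestinal immune network for IgA production", (6,), 0.497, 171.28, 0.467),
    ("Leukocyte transendothelial migration", (2,), 0.303, 89.07, 0.463),
    ("Progesterone-mediated oocyte maturation", (2,), 0.301, 89.07, 0.462),
    ("Cytokine-cytokine receptor interaction", (1, 2, 4, 6), 0.529, 185.95, 0.455),
    ("Jak-STAT signaling pathway", (1, 2, 8, 9), 0.468, 176.12, 0.445),
    ("Renin-angiotensin system", (5,), 0.804, 231.04, 0.443),
    ("MAPK signaling pathway", (8, 9), 0.378, 149.87, 0.439),
    ("Complement and coagulation cascades", (4, 5, 6), 0.708, 225.19, 0.432),
    ("TGF-beta signaling pathway", (6, 8), 0.486, 190.97, 0.427),
    ("Focal adhesion", (2, 6, 7), 0.464, 188.28, 0.422),
    ("Apoptosis", (9,), 0.431, 194.56, 0.396),
    ("Regulation of actin cytoskeleton", (6,), 0.326, 171.28, 0.378),
    ("Natural killer cell mediated cytotoxicity", (8,), 0.453, 210.67, 0.375),
    ("ErbB signaling pathway", (8,), 0.451, 210.67, 0.374),
    ("Fc epsilon RI signaling pathway", (8,), 0.450, 210.67, 0.374),
    ("T cell receptor signaling pathway", (8,), 0.436, 210.67, 0.368),
    ("Neurotrophin signaling pathway", (8, 9), 0.339, 202.61, 0.338),
    ("Toll-like receptor signaling pathway", (4, 8, 9), 0.432, 226.16, 0.335),
    ("NOD-like receptor signaling pathway", (4, 8), 0.510, 241.96, 0.326),
    ("Dorso-ventral axis formation", (8,), 0.331, 210.67, 0.321),
    ("B cell receptor signaling pathway", (8,), 0.328, 210.67, 0.319),
    ("Cell cycle", (9,), 0.252, 194.56, 0.303),
    ("Chemokine signaling pathway", (1, 4, 8), 0.370, 231.37, 0.300),
    ("Gap junction", (5,), 0.351, 231.04, 0.293),
    ("Calcium signaling pathway", (3, 5), 0.363, 237.48, 0.284),
    ("Neuroactive ligand-receptor interaction", (3, 5), 0.343, 237.48, 0.276),
    ("Vascular smooth muscle contraction", (3, 5), 0.327, 237.48, 0.270),
    ("Melanogenesis", (5,), 0.281, 231.04, 0.262),
    ("ECM-receptor interaction", (7,), 0.478, 304.50, 0.040),
]


def pathway_fixture_frame() -> pd.DataFrame:
    """The pathway fixture as a DataFrame indexed by pathway name."""
    return pd.DataFrame(
        PATHWAY_TABLE,
        columns=[
            "pathway",
            "communities",
            "path_gene_score",
            "printed_path_rank_score",
            "printed_path_score",
        ],
    ).set_index("pathway")
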