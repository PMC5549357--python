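"""Combine differential-expression study tables into a cross-study consensus.

Within each study genes are rank-normalized by adjusted p; across studies
GeneAS = sqrt((Narray-1)/(S-1) * mean GeneS) rewards genes reported often
and significantly.  Direction is kept only when every study agrees.
"""

from consenrank import (
    SimConfig,
    cross_study_overlaps,
    microarray_consensus,
    score_study_genes,
    simulate_microarray_studies,
)

config = SimConfig(seed=42)
studies, truth = simulate_microarray_studies(config)

scored = score_study_genes(studies)
table = microarray_consensus(scored)
print(f"{len(table.df)} genes scored across {table.n_studies} studies")
print(f"class counts: {table.class_counts()}")
print("\nstrongest cross-study genes:")
print(table.df.head(8).round(4))

report = cross_study_overlaps(scored)
print("\npairwise study overlaps:")
print(report["pairwise"])
print(f"genes in every study: {report['all_way_count']}")
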