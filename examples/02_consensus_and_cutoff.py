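"""Aggregate ranked gene lists into a consensus and locate a rational cutoff.

Each list is rank-normalized; a gene's consensus score rewards both its
average position and how many sources reported it.  The cutoff index
I = TP/(FP+1) * ConsenScore peaks where true recoveries still outweigh
the false positives accumulated walking down the table.
"""

from consenrank import SimConfig, consensus_scores, rational_cutoff, simulate_method_lists

config = SimConfig(seed=42)
lists, positives = simulate_method_lists(config)

table = consensus_scores(lists)
print(f"consensus over {table.n_genes} genes from {table.n_methods} methods")
print("\ntop of the table:")
print(table.df.head(8)[["n_methods", "gene_score", "rank", "consen_score"]])

found = table.ranks_of(positives)
print(f"\nplanted genes found at median rank {found.median():.0f} (best {found.min():.0f})")

curve = rational_cutoff(table, positives)
print(
    f"rational cutoff at rank {curve.selected_rank} "
    f"(index {curve.selected_index:.3f})"
)
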