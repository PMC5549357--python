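"""Benchmark how early a ranking recognizes a reference gene set.

Detection percentages count reference genes inside the top f-fraction;
BEDROC (with alpha = 1/f) weights each recovery exponentially toward the
top of the list, so it rewards early hits far more than late ones.
"""

import numpy as np

from consenrank import (
    SimConfig,
    bedroc_score,
    consensus_scores,
    enrichment_metrics,
    simulate_method_lists,
)

config = SimConfig(seed=42)
lists, positives = simulate_method_lists(config)
table = consensus_scores(lists)

report = enrichment_metrics(table, positives)
print(f"AUAC {report.auac:.4f}   ROC {report.roc:.4f}")
print(report.per_fraction.to_string(index=False))

# compare the consensus against each contributing list
cons = bedroc_score(
    np.sort(table.ranks_of(positives).to_numpy(dtype=float)), table.n_genes, 100.0
)
print(f"\nconsensus BEDROC(alpha=100): {cons:.4f}")
for rl in lists[:3]:
    ranks = np.array(
        [r for r, g in enumerate(rl.gene_ids, start=1) if g in positives], dtype=float
    )
    print(f"{rl.method_id}: {bedroc_score(ranks, len(rl), 100.0):.4f}")
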