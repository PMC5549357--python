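"""Generate every synthetic input the analysis consumes.

One SimConfig seed drives four independent generators: ranked gene lists
with planted disease genes, a confidence-scored interaction network with
planted clique communities, differential-expression study tables, and a
gene-set collection aligned with the planted communities.
"""

from consenrank import (
    SimConfig,
    simulate_method_lists,
    simulate_microarray_studies,
    simulate_network,
    simulate_pathway_collection,
)

config = SimConfig(seed=42)

lists, positives = simulate_method_lists(config)
print(f"{len(lists)} ranked lists; {len(positives)} planted disease genes")
print(f"first list holds {len(lists[0])} genes, top gene {lists[0].gene_ids[0]}")

edges, communities = simulate_network(config)
print(f"\nnetwork: {len(edges)} scored edges, {len(communities)} planted communities")
print(f"community sizes: {[len(c) for c in communities]}")

studies, truth = simulate_microarray_studies(config)
for name, df in studies.items():
    print(f"study {name}: {len(df)} significant genes")

pathways = simulate_pathway_collection(config, communities)
print(f"\n{len(pathways)} gene sets, e.g. pathway_01 with {len(pathways['pathway_01'])} genes")
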