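"""Detect clique-percolation communities on a confidence-filtered network.

Edges below the confidence cutoff are discarded; k-clique communities are
computed for a range of clique sizes and the size-balance index
S^k = |mean - median| / n_communities selects the working k.
"""

from consenrank import (
    SimConfig,
    build_network,
    community_profiles,
    consensus_scores,
    scan_k,
    simulate_method_lists,
    simulate_network,
)

config = SimConfig(seed=42, community_overlap=0)
edges, planted = simulate_network(config)
net = build_network(edges, cutoff=0.9)
print(f"filtered network: {net.n_nodes} nodes, {net.n_edges} edges")

scan = scan_k(net, range(3, 11))
print(scan.table.to_string(index=False))
print(f"selected k = {scan.selected_k}")

partition = scan.partition()
lists, positives = simulate_method_lists(config)
table = consensus_scores(lists)
profiles = community_profiles(partition, table, reference=positives)
print(profiles.drop(columns="genes").to_string())
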