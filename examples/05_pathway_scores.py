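"""Score pathways through the communities they are over-represented in.

Communities link to pathways by hypergeometric over-representation (BH
q < 0.05).  PathRankScore averages the linked communities' mean consensus
ranks; PathScore combines that (normalized against the worst linked
pathway) with how densely the pathway is covered by well-scored genes.
"""

from consenrank import (
    SimConfig,
    build_network,
    community_pathway_map,
    community_profiles,
    consensus_scores,
    find_k_clique_communities,
    pathway_scores,
    simulate_method_lists,
    simulate_network,
    simulate_pathway_collection,
)

config = SimConfig(seed=42, community_overlap=0)
edges, planted = simulate_network(config)
net = build_network(edges, cutoff=0.9)
partition = find_k_clique_communities(net, k=config.community_size)

lists, _ = simulate_method_lists(config)
table = consensus_scores(lists)
profiles = community_profiles(partition, table)

collection = simulate_pathway_collection(config, planted, n_random_sets=3)
cmap = community_pathway_map(partition, collection, config.gene_universe())
print(f"{len(cmap)} community-pathway links")

scores = pathway_scores(cmap, profiles, table, net, collection)
cols = ["communities", "path_rank_score", "path_gene_score", "path_score"]
print(scores[cols].round(4).to_string())
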