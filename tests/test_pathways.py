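import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from consenrank.config import SimConfig
from consenrank.network import (
    ConfidenceNetwork,
    build_network,
    community_profiles,
    find_k_clique_communities,
)
from consenrank.pathways import (
    community_pathway_map,
    component_significance,
    normalized_rank_term,
    overlap_significance,
    overrepresentation,
    path_gene_score,
    path_rank_score,
    path_score,
    pathway_scores,
)
from consenrank.preeclampsia import (
    COMMUNITY_SUMMARY,
    G1,
    G2,
    pathogenic_reference,
    pathway_fixture_frame,
)
from consenrank.synthetic import simulate_network, simulate_pathway_collection
from conftest import make_table
from oracles import largest_component_bruteforce


class TestOverrepresentation:
    def test_exact_full_overlap_probability(self):
        universe = [f"g{i:02d}" for i in range(50)]
        sets = {"s": set(universe[:5])}
        ora = overrepresentation(universe[:5], universe, sets)
        assert ora.loc["s", "pvalue"] == pytest.approx(1 / math.comb(50, 5))

    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i:02d}" for i in range(50)]
        sets = {"s": set(universe[:5])}
        ora = overrepresentation(universe[40:45], universe, sets)
        assert ora.loc["s", "overlap"] == 0
        assert ora.loc["s", "pvalue"] == pytest.approx(1.0)

    def test_bh_adjustment_properties(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i:03d}" for i in range(200)]
        sets = {
            f"s{j}": set(rng.choice(universe, size=20, replace=False))
            for j in range(10)
        }
        ora = overrepresentation(universe[:30], universe, sets)
        assert (ora["qvalue"] >= ora["pvalue"] - 1e-12).all()
        by_p = ora.sort_values("pvalue")
        assert (np.diff(by_p["qvalue"]) >= -1e-12).all()

    def test_query_outside_universe_errors(self):
        with pytest.raises(ValueError):
            overrepresentation(["zz"], ["a", "b"], {"s": {"a"}})

    def test_empty_query_errors(self):
        with pytest.raises(ValueError):
            overrepresentation([], ["a", "b"], {"s": {"a"}})


def _planted_setup(seed=11, planted_fraction=1.0, n_filler=0, **over):
    base = dict(
        n_genes=300,
        n_positives=15,
        n_methods=4,
        n_communities=3,
        community_size=5,
        community_overlap=0,
        n_network_extra=20,
        n_de_genes=60,
        seed=seed,
    )
    base.update(over)
    config = SimConfig(**base)
    edges, comms = simulate_network(config)
    net = build_network(edges, cutoff=0.9)
    part = find_k_clique_communities(net, k=config.community_size)
    sets = simulate_pathway_collection(
        config, comms, planted_fraction=planted_fraction, n_filler=n_filler
    )
    return config, net, part, comms, sets


class TestCommunityPathwayMap:
    def test_planted_sets_link_to_their_communities(self):
        config, net, part, comms, sets = _planted_setup()
        cmap = community_pathway_map(part, sets, config.gene_universe())
        # each detected community links to the pathway planted on it
        for i, comm in enumerate(part.communities, start=1):
            linked = cmap.pathways_of(i)
            assert any(set(sets[m]) == set(comm) for m in linked)

    def test_zero_threshold_links_nothing(self):
        config, net, part, comms, sets = _planted_setup()
        cmap = community_pathway_map(part, sets, config.gene_universe(), q_threshold=0.0)
        assert len(cmap) == 0

    def test_random_sets_rarely_link(self):
        config, net, part, comms, _ = _planted_setup()
        universe = config.gene_universe()
        rng = np.random.default_rng(4)
        empty = 0
        trials = 60
        for _ in range(trials):
            sets = {
                f"r{j}": set(rng.choice(universe, size=15, replace=False))
                for j in range(5)
            }
            cmap = community_pathway_map(part, sets, universe)
            empty += len(cmap) == 0
        assert empty >= 0.9 * trials


class TestScoringPrimitives:
    def test_rank_score_is_mean_of_community_means(self):
        assert path_rank_score([273.25, 231.04, 171.28]) == pytest.approx(225.19)
        assert path_rank_score([273.25, 210.67]) == pytest.approx(241.96)
        assert path_rank_score([89.07, 171.28]) == pytest.approx(130.175)

    def test_rank_score_empty_errors(self):
        with pytest.raises(ValueError):
            path_rank_score([])

    def test_gene_score_example(self):
        assert path_gene_score(0.9, 2, 10) == pytest.approx(math.sqrt(0.18))

    def test_gene_score_bad_size_errors(self):
        with pytest.raises(ValueError):
            path_gene_score(0.9, 2, 0)

    def test_normalized_rank_term_range(self):
        assert normalized_rank_term(0.0, 300.0) == pytest.approx(301 / 301)
        assert normalized_rank_term(300.0, 300.0) == pytest.approx(1 / 301)

    def test_path_score_published_examples(self):
        p_max = 304.50
        nk = path_score(0.453, 210.67, p_max)
        apoptosis = path_score(0.431, 194.56, p_max)
        assert nk == pytest.approx(0.375, abs=0.005)
        assert apoptosis == pytest.approx(0.396, abs=0.005)


class TestPublishedTableRegression:
    def test_rank_scores_recompute_from_community_summary(self):
        fix = pathway_fixture_frame()
        ok = 0
        for name, row in fix.iterrows():
            recomputed = path_rank_score(
                COMMUNITY_SUMMARY.loc[list(row["communities"]), "mean_rank"]
            )
            ok += abs(recomputed - row["printed_path_rank_score"]) <= 0.02
        # one published row is internally inconsistent with its own
        # community list; every other row reproduces exactly
        assert ok >= 31

    def test_path_scores_recompute_from_printed_components(self):
        fix = pathway_fixture_frame()
        p_max = fix["printed_path_rank_score"].max()
        assert p_max == pytest.approx(304.50)
        for name, row in fix.iterrows():
            recomputed = path_score(
                row["path_gene_score"], row["printed_path_rank_score"], p_max
            )
            assert recomputed == pytest.approx(row["printed_path_score"], abs=0.005)


class TestPathwayScoresIntegration:
    def test_planted_pipeline_table_is_self_consistent(self):
        config, net, part, comms, sets = _planted_setup(n_filler=2)
        universe = config.gene_universe()
        cmap = community_pathway_map(part, sets, universe)
        table = make_table(universe)
        profiles = community_profiles(part, table)
        scores = pathway_scores(cmap, profiles, table, net, sets)
        assert len(scores) >= 3
        valid = scores.dropna(subset=["path_score"])
        assert np.allclose(
            valid["path_score"],
            np.sqrt(valid["path_gene_score"] * valid["norm_rank_term"]),
        )
        assert (np.diff(valid["path_score"]) <= 1e-12).all()
        p_max = scores["path_rank_score"].max()
        assert np.allclose(
            scores["norm_rank_term"],
            (p_max + 1 - scores["path_rank_score"]) / (p_max + 1),
        )

    def test_empty_map_errors(self):
        config, net, part, comms, sets = _planted_setup()
        cmap = community_pathway_map(part, sets, config.gene_universe(), q_threshold=0.0)
        table = make_table(config.gene_universe())
        profiles = community_profiles(part, table)
        with pytest.raises(ValueError):
            pathway_scores(cmap, profiles, table, net, sets)


class TestComponentSignificance:
    def test_connected_input_on_sparse_graph_is_significant(self):
        g = nx.Graph()
        g.add_edges_from([(f"c{i}", f"c{j}") for i in range(6) for j in range(i + 1, 6)])
        g.add_nodes_from(f"x{i}" for i in range(40))
        g.add_edges_from((f"x{i}", f"x{i+1}") for i in range(0, 40, 2))
        res = component_significance(
            [f"c{i}" for i in range(6)], g, allow_missing=0, n_mc=200, seed=0
        )
        assert res.observed_size == 6
        assert res.pvalue < 0.05

    def test_observed_size_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(8, 30))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.05, 0.3)), seed=int(rng.integers(1 << 30)))
            g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in range(n)})
            m = int(rng.integers(2, n))
            subset = [f"n{i:02d}" for i in sorted(rng.choice(n, size=m, replace=False))]
            res = component_significance(subset, g, allow_missing=0, n_mc=100, seed=1)
            assert res.observed_size == largest_component_bruteforce(g, subset)

    def test_one_missing_gene_bridges_a_gap(self):
        g = nx.Graph([("a", "x"), ("x", "b"), ("b", "y"), ("y", "z")])
        strict = component_significance(["a", "b"], g, allow_missing=0, n_mc=100, seed=0)
        relaxed = component_significance(["a", "b"], g, allow_missing=1, n_mc=100, seed=0)
        assert strict.observed_size == 1
        assert relaxed.observed_size == 2

    def test_two_missing_genes_extend_the_reach(self):
        g = nx.path_graph(["a", "x", "y", "b"])
        one = component_significance(["a", "b"], g, allow_missing=1, n_mc=100, seed=0)
        two = component_significance(["a", "b"], g, allow_missing=2, n_mc=100, seed=0)
        assert one.observed_size == 1
        assert two.observed_size == 2

    def test_invalid_arguments_error(self):
        g = nx.path_graph(["a", "b", "c"])
        with pytest.raises(ValueError):
            component_significance(["a"], g, allow_missing=3, n_mc=100)
        with pytest.raises(ValueError):
            component_significance(["a"], g, n_mc=10)
        with pytest.raises(ValueError):
            component_significance(["zz"], g, n_mc=100)


class TestOverlapSignificance:
    def test_identical_sets_maximal_overlap(self):
        universe = [f"g{i:02d}" for i in range(60)]
        a = set(universe[:8])
        res = overlap_significance(a, a, universe, n_perm=499, seed=0)
        assert res.overlap == 8
        assert res.pvalue < 0.05
        assert res.pvalue_hypergeom == pytest.approx(
            1 / math.comb(60, 8), rel=1e-9
        )

    def test_expected_overlap_formula(self):
        universe = [f"g{i:02d}" for i in range(60)]
        res = overlap_significance(universe[:10], universe[20:35], universe, n_perm=199)
        assert res.expected == pytest.approx(10 * 15 / 60)

    def test_permutation_tracks_hypergeometric(self):
        universe = [f"g{i:03d}" for i in range(100)]
        a = universe[:12]
        b = universe[8:28]
        res = overlap_significance(a, b, universe, n_perm=4999, seed=2)
        assert abs(res.pvalue - res.pvalue_hypergeom) < 0.05

    def test_sets_outside_universe_error(self):
        with pytest.raises(ValueError):
            overlap_significance({"zz"}, {"a"}, ["a", "b"])

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            overlap_significance(set(), set(), [])


class TestPathogenicReference:
    def test_union_has_35_unique_genes(self):
        ref = pathogenic_reference("G1,2")
        assert len(ref.members) == 35
        assert len(set(G1) | set(G2)) == 35

    def test_component_sizes(self):
        assert len(pathogenic_reference("G1").members) == 27
        assert len(pathogenic_reference("G2").members) == 13

    def test_shared_genes_between_sources(self):
        shared = set(G1) & set(G2)
        assert shared == {"NOS3", "VEGFA", "TGFB1", "AGTR1", "IL10"}

    def test_unknown_selector_errors(self):
        with pytest.raises(ValueError):
            pathogenic_reference("G3")
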