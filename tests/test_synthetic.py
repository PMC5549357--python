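import dataclasses
import math

import numpy as np
import pytest

from consenrank.benchmark import bedroc_score
from consenrank.config import SimConfig
from consenrank.consensus import consensus_scores
from consenrank.io import read_gmt, write_gmt
from consenrank.microarray import microarray_consensus, score_study_genes
from consenrank.network import build_network, find_k_clique_communities
from consenrank.synthetic import (
    simulate_method_lists,
    simulate_microarray_studies,
    simulate_network,
    simulate_pathway_collection,
)


def cfg(**over):
    base = dict(
        n_genes=300,
        n_positives=15,
        n_methods=4,
        n_communities=3,
        community_size=5,
        community_overlap=0,
        n_network_extra=20,
        n_de_genes=60,
        seed=11,
    )
    base.update(over)
    return SimConfig(**base)


class TestDeterminism:
    def test_same_seed_reproduces_everything(self):
        c = cfg()
        lists1, pos1 = simulate_method_lists(c)
        lists2, pos2 = simulate_method_lists(c)
        assert pos1 == pos2
        for a, b in zip(lists1, lists2):
            assert a.gene_ids == b.gene_ids and np.array_equal(a.scores, b.scores)
        e1, c1 = simulate_network(c)
        e2, c2 = simulate_network(c)
        assert e1.equals(e2) and c1 == c2
        s1, t1 = simulate_microarray_studies(c)
        s2, t2 = simulate_microarray_studies(c)
        assert t1 == t2
        for k in s1:
            assert s1[k].equals(s2[k])
        assert simulate_pathway_collection(c, c1) == simulate_pathway_collection(c, c2)

    def test_different_seeds_differ(self):
        lists1, pos1 = simulate_method_lists(cfg(seed=1))
        lists2, pos2 = simulate_method_lists(cfg(seed=2))
        assert pos1 != pos2 or lists1[0].gene_ids != lists2[0].gene_ids

    def test_generators_use_independent_streams(self):
        # changing network geometry must not perturb the ranked lists
        c1, c2 = cfg(), cfg(n_communities=5, community_size=6)
        a, _ = simulate_method_lists(c1)
        b, _ = simulate_method_lists(c2)
        for x, y in zip(a, b):
            assert x.gene_ids == y.gene_ids


class TestMethodLists:
    def test_noise_free_perfect_signal_puts_positives_first(self):
        c = cfg(signal_a=math.inf, noise_sd=0.0)
        lists, positives = simulate_method_lists(c)
        for rl in lists:
            flags = [g in positives for g in rl.gene_ids]
            n_pos = sum(flags)
            assert all(flags[:n_pos]) and not any(flags[n_pos:])

    def test_coverage_one_includes_every_gene(self):
        c = cfg(coverage_pos=1.0, coverage_neg=1.0)
        lists, _ = simulate_method_lists(c)
        for rl in lists:
            assert len(rl.gene_ids) == c.n_genes

    def test_positive_count_matches_config(self):
        _, positives = simulate_method_lists(cfg())
        assert len(positives) == 15

    def test_null_signal_leaves_positives_unenriched(self):
        # signal_a = 1 makes positives indistinguishable; their mean
        # normalized list position should average 0.5 across seeds
        means = []
        for seed in range(100):
            c = cfg(signal_a=1.0, coverage_pos=0.5, coverage_neg=0.5, seed=seed)
            lists, positives = simulate_method_lists(c)
            vals = []
            for rl in lists:
                M = len(rl.gene_ids)
                vals.extend(
                    (r + 1) / M for r, g in enumerate(rl.gene_ids) if g in positives
                )
            means.append(np.mean(vals))
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - 0.5) < 3 * se

    def test_stronger_signal_raises_consensus_bedroc(self):
        def mean_bedroc(a):
            out = []
            for seed in range(20):
                c = cfg(signal_a=a, seed=seed)
                lists, positives = simulate_method_lists(c)
                table = consensus_scores(lists, n_methods=c.n_methods)
                ranks = table.ranks_of(positives)
                out.append(bedroc_score(np.asarray(ranks), len(table.df), 20.0))
            return np.mean(out)

        assert mean_bedroc(8.0) > mean_bedroc(1.0)


class TestNetwork:
    def test_planted_edge_count_without_background(self):
        c = cfg(background_edge_prob=0.0)
        edges, comms = simulate_network(c)
        # 3 disjoint 5-cliques: 3 * C(5,2) edges
        assert len(edges) == 3 * 10
        assert [len(x) for x in comms] == [5, 5, 5]
        assert (edges["combined_score"] >= c.intra_score_low).all()

    def test_overlap_shares_nodes_between_consecutive_communities(self):
        c = cfg(community_overlap=2)
        _, comms = simulate_network(c)
        for a, b in zip(comms, comms[1:]):
            assert len(a & b) == 2

    def test_background_scores_below_planted_range(self):
        c = cfg(background_edge_prob=0.5)
        edges, comms = simulate_network(c)
        planted = set().union(*comms)
        bg = edges[
            ~(edges["protein1"].isin(planted) & edges["protein2"].isin(planted))
        ]
        assert len(bg) > 0
        assert (bg["combined_score"] < c.intra_score_low).all()

    def test_confidence_filter_recovers_planted_communities(self):
        c = cfg(background_edge_prob=0.05, seed=3)
        edges, comms = simulate_network(c)
        net = build_network(edges, cutoff=0.9)
        part = find_k_clique_communities(net, k=c.community_size)
        assert sorted(part.communities, key=sorted) == sorted(
            (frozenset(x) for x in comms), key=sorted
        )

    def test_overlap_k_minus_one_merges_chain(self):
        c = cfg(
            n_communities=5,
            community_size=5,
            community_overlap=4,
            background_edge_prob=0.0,
        )
        edges, comms = simulate_network(c)
        net = build_network(edges, cutoff=0.9)
        part = find_k_clique_communities(net, k=5)
        assert len(part) == 1
        assert part.communities[0] == frozenset().union(*comms)

    def test_universe_too_small_errors(self):
        c = cfg(n_genes=20, n_positives=5, n_network_extra=10, n_de_genes=10)
        with pytest.raises(ValueError):
            simulate_network(c)


class TestMicroarrayStudies:
    def test_full_inclusion_gives_complete_tables(self):
        c = cfg(study_inclusion_prob=1.0)
        studies, truth = simulate_microarray_studies(c)
        for df in studies.values():
            assert sorted(df["gene_id"]) == truth["de_pool"]
        table = microarray_consensus(score_study_genes(studies))
        assert (table.df["n_arrays"] == c.n_studies).all()

    def test_no_sign_flips_means_no_ambiguous_genes(self):
        c = cfg(sign_flip_prob=0.0)
        studies, truth = simulate_microarray_studies(c)
        table = microarray_consensus(score_study_genes(studies))
        assert "ambiguous" not in table.class_counts()
        for g, d in table.df["direction"].items():
            assert d == truth["true_direction"][g]

    def test_ambiguous_count_matches_analytic_expectation(self):
        # a pool gene lands in k of S studies ~ Binomial(S, p); each copy
        # flips with prob q; the gene is ambiguous iff both signs occur:
        # P = 1 - q^k - (1-q)^k.  Check the mean count over many seeds.
        S, p, q, n_de = 4, 0.7, 0.15, 60
        expected = n_de * sum(
            math.comb(S, k) * p**k * (1 - p) ** (S - k) * (1 - q**k - (1 - q) ** k)
            for k in range(1, S + 1)
        )
        counts = []
        for seed in range(300):
            c = cfg(
                n_studies=S,
                study_inclusion_prob=p,
                sign_flip_prob=q,
                n_de_genes=n_de,
                seed=seed,
            )
            studies, _ = simulate_microarray_studies(c)
            table = microarray_consensus(score_study_genes(studies))
            counts.append(table.class_counts().get("ambiguous", 0))
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_adjusted_p_within_significance_range(self):
        studies, _ = simulate_microarray_studies(cfg())
        for df in studies.values():
            assert ((df["adjusted_p"] > 0) & (df["adjusted_p"] < 0.05)).all()


class TestPathwayCollection:
    def test_full_fraction_no_filler_reproduces_communities(self):
        c = cfg()
        _, comms = simulate_network(c)
        sets = simulate_pathway_collection(c, comms, planted_fraction=1.0, n_filler=0)
        assert list(sets.values()) == [set(x) for x in comms]

    def test_zero_fraction_no_filler_yields_nothing(self):
        c = cfg()
        _, comms = simulate_network(c)
        sets = simulate_pathway_collection(c, comms, planted_fraction=0.0, n_filler=0)
        assert sets == {}

    def test_random_sets_have_requested_size(self):
        c = cfg()
        sets = simulate_pathway_collection(
            c, None, n_random_sets=4, random_set_size=15
        )
        assert len(sets) == 4 and all(len(s) == 15 for s in sets.values())

    def test_invalid_fraction_errors(self):
        with pytest.raises(ValueError):
            simulate_pathway_collection(cfg(), None, planted_fraction=1.5)

    def test_gmt_round_trip(self, tmp_path):
        c = cfg()
        _, comms = simulate_network(c)
        sets = simulate_pathway_collection(c, comms, n_random_sets=2)
        path = tmp_path / "sets.gmt"
        write_gmt(sets, path)
        assert read_gmt(path) == sets


class TestConfigValidation:
    def test_probability_out_of_range(self):
        with pytest.raises(Exception):
            cfg(coverage_pos=1.5).validate()

    def test_positives_must_fit_universe(self):
        with pytest.raises(Exception):
            cfg(n_positives=300).validate()

    def test_overlap_below_size(self):
        with pytest.raises(Exception):
            cfg(community_overlap=5).validate()
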