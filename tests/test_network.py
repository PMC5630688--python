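"""Similarity graph, MCL clustering, representatives, search, link stats."""

import itertools

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from islet import network
from islet.network import IslandCluster
from islet.oup import OUPattern, pattern_similarity


def _shifted_pattern(base_order, n_swaps, rng):
    """A pattern derived from ``base_order`` by a few adjacent swaps."""
    order = list(base_order)
    for _ in range(n_swaps):
        i = int(rng.integers(0, len(order) - 1))
        order[i], order[i + 1] = order[i + 1], order[i]
    return OUPattern.from_ordering(order)


@pytest.fixture(scope="module")
def planted_patterns():
    """3 groups of 10 patterns; within-group sim > 80, between < 70."""
    rng = np.random.default_rng(5)
    words = [f"w{i:02d}" for i in range(40)]
    patterns, labels = {}, {}
    for g in range(3):
        base = list(words)
        rng.shuffle(base)
        for k in range(10):
            pid = f"g{g}m{k}"
            patterns[pid] = _shifted_pattern(base, n_swaps=20, rng=rng)
            labels[pid] = g
    # verify the construction premise once
    sims_within = [
        pattern_similarity(patterns[a], patterns[b])
        for a, b in itertools.combinations(patterns, 2)
        if labels[a] == labels[b]
    ]
    sims_between = [
        pattern_similarity(patterns[a], patterns[b])
        for a, b in itertools.combinations(patterns, 2)
        if labels[a] != labels[b]
    ]
    assert min(sims_within) > 80 and max(sims_between) < 70
    return patterns, labels


class TestBuildGraph:
    def test_identical_patterns_capped_at_ceiling(self):
        p = OUPattern.from_ordering([f"w{i}" for i in range(10)])
        g = network.build_graph({"a": p, "b": p})
        assert g["a"]["b"]["raw"] == 100.0
        assert g["a"]["b"]["weight"] == 85.0

    def test_pair_below_floor_has_no_edge(self):
        words = [f"w{i}" for i in range(10)]
        a = OUPattern.from_ordering(words)
        b = OUPattern.from_ordering(list(reversed(words)))
        g = network.build_graph({"a": a, "b": b})
        assert g.number_of_edges() == 0

    def test_planted_groups_form_three_components(self, planted_patterns):
        patterns, labels = planted_patterns
        g = network.build_graph(patterns)
        comps = list(nx.connected_components(g))
        assert len(comps) == 3
        for comp in comps:
            assert len({labels[m] for m in comp}) == 1


class TestMCL:
    def test_two_disjoint_cliques(self):
        g = nx.Graph()
        for grp, members in enumerate([list("abcd"), list("wxyz")]):
            for u, v in itertools.combinations(members, 2):
                g.add_edge(u, v, weight=85.0, raw=90.0)
        clusters = network.mcl(g)
        assert sorted(sorted(c.members) for c in clusters) == [list("abcd"), list("wxyz")]

    def test_single_node(self):
        g = nx.Graph()
        g.add_node("solo")
        clusters = network.mcl(g)
        assert len(clusters) == 1 and clusters[0].members == ["solo"]

    def test_planted_partition_recovered_exactly(self, planted_patterns):
        patterns, labels = planted_patterns
        g = network.build_graph(patterns)
        clusters = network.mcl(g)
        pred = {m: ci for ci, c in enumerate(clusters) for m in c.members}
        ids = sorted(patterns)
        ari = adjusted_rand_score([labels[i] for i in ids], [pred[i] for i in ids])
        assert ari == 1.0

    def test_partition_property_and_node_order_invariance(self, planted_patterns):
        patterns, _ = planted_patterns
        g = network.build_graph(patterns)
        clusters = network.mcl(g)
        all_members = sorted(m for c in clusters for m in c.members)
        assert all_members == sorted(patterns)
        # permuted node insertion order must not change the partition
        g2 = nx.Graph()
        rng = np.random.default_rng(0)
        nodes = list(g.nodes)
        rng.shuffle(nodes)
        g2.add_nodes_from(nodes)
        edges = list(g.edges(data=True))
        rng.shuffle(edges)
        g2.add_edges_from(edges)
        clusters2 = network.mcl(g2)
        assert sorted(tuple(c.members) for c in clusters) == sorted(
            tuple(c.members) for c in clusters2
        )


class TestSubcluster:
    def _clique_graph(self, groups, bridge_pairs=(), within=85.0, bridge=75.0):
        g = nx.Graph()
        for members in groups:
            for u, v in itertools.combinations(members, 2):
                g.add_edge(u, v, weight=within, raw=within)
        for u, v in bridge_pairs:
            g.add_edge(u, v, weight=bridge, raw=bridge)
        return g

    def test_small_cluster_untouched(self):
        members = [f"m{i}" for i in range(49)]
        g = self._clique_graph([members])
        clusters = [IslandCluster("C1", members)]
        network.subcluster(clusters, g)
        assert clusters[0].subclusters == []

    def test_large_cluster_split_conserves_members(self):
        members = [f"m{i}" for i in range(51)]
        g = self._clique_graph([members])
        clusters = [IslandCluster("C1", members)]
        network.subcluster(clusters, g)
        assert clusters[0].subclusters
        sub_members = sorted(m for s in clusters[0].subclusters for m in s.members)
        assert sub_members == sorted(members)

    def test_weakly_bridged_groups_separate_at_sub_level(self):
        a = [f"a{i}" for i in range(30)]
        b = [f"b{i}" for i in range(30)]
        g = self._clique_graph([a, b], bridge_pairs=[("a0", "b0"), ("a1", "b1")])
        clusters = [IslandCluster("C1", sorted(a + b))]
        network.subcluster(clusters, g)
        truth = {m: m[0] for m in a + b}
        pred = {
            m: si for si, s in enumerate(clusters[0].subclusters) for m in s.members
        }
        ids = sorted(a + b)
        assert adjusted_rand_score(
            [truth[i] for i in ids], [pred[i] for i in ids]
        ) == 1.0


class TestRepresentatives:
    def test_uniform_clique_needs_one_representative(self):
        g = nx.Graph()
        members = list("abcde")
        for u, v in itertools.combinations(members, 2):
            g.add_edge(u, v, weight=80.0, raw=80.0)
        reps = network.select_representatives(members, g)
        assert len(reps) == 1

    def test_singleton_represents_itself(self):
        g = nx.Graph()
        g.add_node("one")
        assert network.select_representatives(["one"], g) == ["one"]

    def test_star_topology_selects_hub(self):
        g = nx.Graph()
        leaves = [f"leaf{i}" for i in range(6)]
        for leaf in leaves:
            g.add_edge("hub", leaf, weight=80.0, raw=80.0)
        reps = network.select_representatives(["hub"] + leaves, g)
        assert reps == ["hub"]

    def test_cover_property_on_corpus_clustering(self, corpus_clustering):
        g, clusters = corpus_clustering
        for cl in clusters:
            for unit in cl.search_units():
                assert unit.representatives
                for m in unit.members:
                    assert any(
                        m == r
                        or (g.has_edge(m, r) and g[m][r]["raw"] >= 75.0)
                        for r in unit.representatives
                    )


class TestHeuristicSearch:
    def test_member_query_returns_itself_at_100(self, corpus_patterns, corpus_clustering):
        patterns, _, _ = corpus_patterns
        _, clusters = corpus_clustering
        member = sorted(patterns)[0]
        hits = dict(network.heuristic_search(patterns[member], clusters, patterns))
        assert hits[member] == 100.0

    def test_dissimilar_query_returns_empty(self, corpus_patterns, corpus_clustering):
        patterns, _, _ = corpus_patterns
        _, clusters = corpus_clustering
        words = next(iter(patterns.values())).words
        alien = OUPattern.from_ordering(tuple(reversed(words)))
        assert network.heuristic_search(alien, clusters, patterns) == []

    def test_hits_are_subset_of_exhaustive_scan(self, corpus_patterns, corpus_clustering):
        patterns, _, _ = corpus_patterns
        _, clusters = corpus_clustering
        ids = sorted(patterns)
        for q in ids[::30]:
            exhaustive = {
                m
                for m in ids
                if pattern_similarity(patterns[q], patterns[m]) >= 75.0
            }
            hits = {m for m, _s in network.heuristic_search(patterns[q], clusters, patterns)}
            assert hits <= exhaustive

    def test_recall_against_exhaustive_oracle(self, corpus_patterns, corpus_clustering):
        patterns, _, _ = corpus_patterns
        _, clusters = corpus_clustering
        ids = sorted(patterns)
        found = total = 0
        for q in ids[::5]:
            exhaustive = {
                m
                for m in ids
                if m != q and pattern_similarity(patterns[q], patterns[m]) >= 75.0
            }
            hits = {m for m, _s in network.heuristic_search(patterns[q], clusters, patterns)}
            total += len(exhaustive)
            found += len(exhaustive & hits)
        assert found / total >= 0.9


class TestSequenceLinks:
    def _write(self, tmp_path, rows):
        p = tmp_path / "blast.tsv"
        p.write_text("\n".join("\t".join(map(str, r)) for r in rows) + "\n")
        return p

    def _row(self, q, s, evalue):
        return [q, s, 98.0, 500, 2, 0, 1, 500, 1, 500, evalue, 900.0]

    def test_three_row_toy_file(self, tmp_path):
        p = self._write(
            tmp_path,
            [
                self._row("A", "A", 1e-30),   # self hit: dropped
                self._row("A", "B", 1e-8),    # passes
                self._row("A", "C", 1e-5),    # fails the cutoff
            ],
        )
        links = network.read_sequence_links(p)
        assert links == {("A", "B"): 1e-8}

    def test_reciprocal_rows_collapse(self, tmp_path):
        p = self._write(
            tmp_path, [self._row("A", "B", 1e-8), self._row("B", "A", 1e-12)]
        )
        links = network.read_sequence_links(p)
        assert links == {("A", "B"): 1e-12}

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("A\tB\tnot-enough-columns\n")
        with pytest.raises(ValueError, match="line 1"):
            network.read_sequence_links(p)


class TestLinkProfile:
    def test_same_replicon_links_are_genome_level(self):
        prof = network.link_profile(
            [("i1", "i2", 90.0)],
            [],
            hosts={"i1": "G1", "i2": "G1"},
            lineages={"G1": "D0;P0;O0;F0;G0;s0;st0"},
        )
        t = prof.rank_table.set_index("level")
        assert t.loc["Genome", "count"] == 1

    def test_strain_level_assignment(self):
        lin_a = "Bacteria;Proteobacteria;Enterobacterales;Enterobacteriaceae;Escherichia;coli;K12"
        lin_b = "Bacteria;Proteobacteria;Enterobacterales;Enterobacteriaceae;Escherichia;coli;O157"
        prof = network.link_profile(
            [("i1", "i2", 80.0)],
            [],
            hosts={"i1": "G1", "i2": "G2"},
            lineages={"G1": lin_a, "G2": lin_b},
        )
        t = prof.rank_table.set_index("level")
        assert t.loc["Strain", "count"] == 1

    def test_counts_match_brute_force_recount(self, corpus_patterns, default_corpus):
        patterns, _, host_of = corpus_patterns
        lineages = {g.id: g.truth.lineage for g in default_corpus.genomes}
        ids = sorted(patterns)[:80]
        links = []
        for a, b in itertools.combinations(ids, 2):
            s = pattern_similarity(patterns[a], patterns[b])
            if s >= 75.0:
                links.append((a, b, s))
        seq_links = {(ids[0], ids[1]): 1e-9}
        prof = network.link_profile(links, seq_links, host_of, lineages)

        # independent recount: per-island degree and per-level totals
        for _i, row in prof.per_island.iterrows():
            deg = sum(1 for a, b, _s in links if row["island"] in (a, b))
            assert row["n_oup_links"] == deg
        ranks = ["Domain", "Phylum", "Order", "Family", "Genus", "Species", "Strain"]

        def level(a, b):
            if host_of[a] == host_of[b]:
                return "Genome"
            fa = lineages[host_of[a]].split(";")
            fb = lineages[host_of[b]].split(";")
            for r, x, y in zip(ranks, fa, fb):
                if x != y:
                    return r
            return "Strain"

        t = prof.rank_table.set_index("level")
        for lvl in network.TAXONOMIC_LEVELS:
            expected = sum(1 for a, b, _s in links if level(a, b) == lvl)
            assert t.loc[lvl, "count"] == expected

    def test_island_without_lineage_kept_in_counts_only(self):
        prof = network.link_profile(
            [("i1", "i2", 90.0)],
            [],
            hosts={"i1": "G1", "i2": "G2"},
            lineages={"G1": "D;P;O;F;G;s;st"},
        )
        assert set(prof.per_island["island"]) == {"i1", "i2"}
        assert prof.rank_table["count"].sum() == 0
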