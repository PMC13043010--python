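"""Total-Tw conservation, representative/dominant term selection, the
optimal-subnetwork scan, and ontology clustering."""

import numpy as np
import pytest

from ontonet.enrichment import fisher_enrichment
from ontonet.genesets import build_profiles
from ontonet.interpret import (
    cluster_ontology,
    dominant_term,
    optimal_subnet,
    representative_terms,
    term_total_tw,
    term_totals,
)
from ontonet.network import build_network, decompose
from ontonet.similarity import EdgeRecord, pairwise_edges, t_score

from conftest import make_collection, random_case


def build_case(rng, list_size=14):
    coll, genes, table, profiles = random_case(rng, list_size=list_size)
    net = build_network(genes, pairwise_edges(genes, profiles, table))
    return coll, genes, table, net


class TestTermTotalTw:
    def test_unshared_term_is_zero_with_warning(self, rng, caplog):
        _, _, _, net = build_case(rng)
        with caplog.at_level("WARNING"):
            assert term_total_tw(net, "no_such_term") == 0.0
        assert "no edge" in caplog.text

    def test_contribution_times_tw_allocation(self):
        net = build_network(
            ["a", "b", "c"],
            [
                EdgeRecord("a", "b", 0.4, {"T": 0.5, "U": 0.5}),
                EdgeRecord("b", "c", 0.4, {"T": 0.5, "U": 0.5}),
            ],
        )
        assert term_total_tw(net, "T") == pytest.approx(0.4)

    def test_fraction_mode_sums_contributions(self):
        net = build_network(
            ["a", "b"], [EdgeRecord("a", "b", 0.4, {"T": 0.25, "U": 0.75})]
        )
        assert term_total_tw(net, "U", mode="fraction") == pytest.approx(0.75)

    def test_conservation_over_random_networks(self, rng):
        """Sum over terms of total Tw equals sum over edges of Tw exactly."""
        for _ in range(10):
            _, _, _, net = build_case(rng)
            totals = term_totals(net)
            assert sum(totals.values()) == pytest.approx(
                sum(e.tw for e in net.edges), abs=1e-9
            )


class TestRepresentativeTerms:
    def brute_force_greedy(self, net, table, coll, crit=(2.0, 1.0, 0.3)):
        min_p, min_tw, max_t = crit
        totals = term_totals(net)
        weights = table.weights()
        cands = [
            t for t in totals if totals[t] > min_tw and weights.get(t, 0) > min_p
        ]
        cands.sort(key=lambda t: (-totals[t], -weights[t], t))
        out = []
        for t in cands:
            if all(
                t_score(coll.terms[t].genes, coll.terms[u].genes) < max_t for u in out
            ):
                out.append(t)
        return out

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(15):
            coll, _, table, net = build_case(rng)
            sel = representative_terms(net, table, coll)
            assert sel.term_ids() == self.brute_force_greedy(net, table, coll)

    def test_selection_always_satisfies_criteria(self, rng):
        for _ in range(10):
            coll, _, table, net = build_case(rng)
            sel = representative_terms(net, table, coll)
            chosen = sel.selected
            for s in chosen:
                assert s.neg_log_p > sel.min_neg_log_p
                assert s.total_tw > sel.min_total_tw
            for i, a in enumerate(chosen):
                for b in chosen[i + 1 :]:
                    t = t_score(coll.terms[a.term_id].genes, coll.terms[b.term_id].genes)
                    assert t < sel.max_pairwise_t

    def test_identical_gene_sets_filtered(self):
        coll = make_collection(
            {"A": {"a", "b", "c"}, "B": {"a", "b", "c"}},
            extra_universe={f"x{i}" for i in range(20)},
        )
        genes = ["a", "b", "c"]
        table = fisher_enrichment(genes, coll)
        profiles = build_profiles(coll, genes)
        net = build_network(genes, pairwise_edges(genes, profiles, table))
        sel = representative_terms(net, table, coll, min_total_tw=0.0)
        assert len(sel) == 1  # duplicate term has T = 1 >= 0.3

    def test_no_candidates_gives_empty_selection(self, rng):
        coll, _, table, net = build_case(rng)
        sel = representative_terms(net, table, coll, min_total_tw=1e9)
        assert len(sel) == 0

    def test_relaxing_t_filter_never_shrinks_selection(self, rng):
        coll, _, table, net = build_case(rng)
        prev: set[str] = set()
        for max_t in (0.1, 0.3, 0.6, 1.01):
            sel = set(representative_terms(net, table, coll, max_pairwise_t=max_t).term_ids())
            assert prev <= sel
            prev = sel


class TestDominantTerm:
    def test_largest_coverage_wins_over_enrichment(self):
        """A broader term dominates a more significant but smaller one."""
        coll = make_collection(
            {
                "BROAD": {"a", "b", "c", "d", "e"},
                "SHARP": {"a", "b", "c"},
            },
            extra_universe={f"x{i}" for i in range(40)},
        )
        genes = ["a", "b", "c", "d", "e"]
        table = fisher_enrichment(genes, coll)
        profiles = build_profiles(coll, genes)
        net = build_network(genes, pairwise_edges(genes, profiles, table))
        sub = decompose(net, 0.0, 0)[0]
        assert dominant_term(sub, coll, table) == "BROAD"

    def test_coverage_tie_broken_by_enrichment(self, rng):
        coll = make_collection(
            {"P": {"a", "b", "c"}, "Q": {"a", "b", "c", "z1", "z2"}},
            extra_universe={f"x{i}" for i in range(20)},
        )
        genes = ["a", "b", "c"]
        table = fisher_enrichment(genes, coll)
        profiles = build_profiles(coll, genes)
        net = build_network(genes, pairwise_edges(genes, profiles, table))
        sub = decompose(net, 0.0, 0)[0]
        # both cover 3 genes; P (smaller term) is more enriched
        assert table.rows["P"].weight > table.rows["Q"].weight
        assert dominant_term(sub, coll, table) == "P"

    def test_no_covering_term_rejected(self, tiny_collection):
        from ontonet.network import Subnetwork

        table = fisher_enrichment(["RPL7"], tiny_collection)
        sub = Subnetwork(genes=frozenset({"LSM10"}), edges=(), threshold=0.0)
        with pytest.raises(ValueError):
            dominant_term(sub, tiny_collection, table)


class TestOptimalSubnet:
    def test_engineered_fixture_returns_known_component(self):
        """Two well-labeled dedicated terms cover one module; the scan must
        find that module and satisfy its postconditions."""
        coll = make_collection(
            {
                # one bridging gene keeps the term-term Tanimoto at 1/7 < 0.3
                "M1": {"a", "b", "c", "d"},
                "M2": {"d", "e", "f", "g"},
                "OTHER": {"p", "q", "r"},
            },
            extra_universe={f"x{i}" for i in range(60)},
        )
        genes = ["a", "b", "c", "d", "e", "f", "g", "p", "q", "r"]
        table = fisher_enrichment(genes, coll)
        profiles = build_profiles(coll, genes)
        net = build_network(genes, pairwise_edges(genes, profiles, table))
        opt = optimal_subnet(net, table, coll, min_total_tw=0.5)
        assert opt is not None
        assert opt.subnetwork.genes == frozenset("abcdefg")
        assert opt.labeled_ratio > 0.8
        assert len(opt.representative_terms) >= 2
        assert all(e.tw > opt.threshold for e in opt.subnetwork.edges)

    def test_single_shared_term_network_has_no_optimum(self):
        coll = make_collection(
            {"ONLY": {"a", "b", "c", "d"}}, extra_universe={f"x{i}" for i in range(30)}
        )
        genes = ["a", "b", "c", "d"]
        table = fisher_enrichment(genes, coll)
        profiles = build_profiles(coll, genes)
        net = build_network(genes, pairwise_edges(genes, profiles, table))
        assert optimal_subnet(net, table, coll) is None

    def test_postconditions_on_random_fixtures(self, rng):
        for _ in range(10):
            coll, _, table, net = build_case(rng)
            opt = optimal_subnet(net, table, coll, min_total_tw=0.3)
            if opt is None:
                continue
            assert opt.labeled_ratio > 0.8
            assert len(opt.representative_terms) >= 2
            assert all(e.tw > opt.threshold for e in opt.subnetwork.edges)


class TestClusterOntology:
    def test_disjoint_terms_are_singletons(self):
        coll = make_collection(
            {"A": {"a", "b", "c"}, "B": {"d", "e", "f"}, "C": {"g", "h", "i"}}
        )
        cl = cluster_ontology(["A", "B", "C"], coll, t_threshold=0.1)
        assert all(len(c) == 1 for c in cl.clusters)

    def test_identical_terms_cluster_together(self):
        coll = make_collection({"A": {"a", "b", "c"}, "B": {"a", "b", "c"}})
        cl = cluster_ontology(["A", "B"], coll, t_threshold=0.5)
        assert frozenset({"A", "B"}) in cl.clusters

    def test_matches_brute_force_components(self, rng):
        import networkx as nx

        for _ in range(10):
            coll, _, table, _ = build_case(rng)
            terms = sorted(coll.terms)[:15]
            thr = float(rng.uniform(0.05, 0.5))
            cl = cluster_ontology(terms, coll, thr, table)
            g = nx.Graph()
            g.add_nodes_from(terms)
            for i, a in enumerate(terms):
                for b in terms[i + 1 :]:
                    if t_score(coll.terms[a].genes, coll.terms[b].genes) > thr:
                        g.add_edge(a, b)
            expected = {frozenset(c) for c in nx.connected_components(g)}
            assert set(cl.clusters) == expected

    def test_exemplar_is_most_enriched_with_table(self, rng):
        coll, genes, table, _ = build_case(rng)
        terms = sorted(table.rows)
        cl = cluster_ontology(terms, coll, 0.05, table)
        weights = table.weights()
        for comp, ex in zip(cl.clusters, cl.exemplars):
            assert weights.get(ex, 0) == max(weights.get(t, 0) for t in comp)
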