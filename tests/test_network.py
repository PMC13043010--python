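"""Network assembly, thresholding/decomposition, node metrics, consensus
networks, layout determinism, and export round trips."""

import numpy as np
import pytest

from ontonet.enrichment import fisher_enrichment
from ontonet.genesets import build_profiles
from ontonet.network import (
    attribute_correlation,
    build_consensus_network,
    build_network,
    decompose,
    export_network,
    import_network,
    layout,
    node_metrics,
)
from ontonet.similarity import EdgeRecord, pairwise_edges

from conftest import make_collection, random_case


def make_net(rng, list_size=12, tw_cutoff=0.0, attrs=None):
    coll, genes, table, profiles = random_case(rng, list_size=list_size)
    edges = pairwise_edges(genes, profiles, table)
    net = build_network(genes, edges, tw_cutoff=tw_cutoff, node_attrs=attrs)
    return coll, genes, table, profiles, net


class TestBuildNetwork:
    def test_default_cutoff_keeps_all_positive_edges(self, rng):
        _, genes, _, _, net = make_net(rng)
        assert all(e.tw > 0 for e in net.edges)
        assert set(net.nodes) == set(genes)  # isolated nodes kept

    def test_strict_inequality_at_cutoff(self):
        edges = [
            EdgeRecord("a", "b", 0.5, {"t": 1.0}),
            EdgeRecord("a", "c", 1.0, {"t": 1.0}),
        ]
        net = build_network(["a", "b", "c"], edges, tw_cutoff=0.5)
        assert [e.key for e in net.edges] == [("a", "c")]
        assert build_network(["a", "b", "c"], edges, tw_cutoff=1.0).edges == []

    def test_invalid_node_type_rejected(self):
        with pytest.raises(ValueError):
            build_network(["a"], [], node_types={"a": 6})


class TestDecompose:
    def test_nesting_and_refinement(self, rng):
        """Raising the threshold only removes edges, and every
        high-threshold component lies inside one low-threshold component."""
        _, _, _, _, net = make_net(rng, list_size=15)
        lo, hi = 0.05, 0.25
        e_lo = {e.key for s in decompose(net, lo, 0) for e in s.edges}
        e_hi = {e.key for s in decompose(net, hi, 0) for e in s.edges}
        assert e_hi <= e_lo
        comps_lo = decompose(net, lo, 0)
        for sub_hi in decompose(net, hi, 0):
            assert any(sub_hi.genes <= c.genes for c in comps_lo)

    def test_node_count_conserved_by_thresholding(self, rng):
        _, genes, _, _, net = make_net(rng)
        subs = decompose(net, 0.9, min_nodes=0)
        assert sum(s.size for s in subs) == len(genes)

    def test_min_nodes_filter_and_ordering(self):
        edges = [
            EdgeRecord("a", "b", 0.9, {"t": 1.0}),
            EdgeRecord("c", "d", 0.9, {"t": 1.0}),
            EdgeRecord("d", "e", 0.9, {"t": 1.0}),
        ]
        net = build_network(list("abcdef"), edges)
        subs = decompose(net, 0.1, min_nodes=1)
        assert [sorted(s.genes) for s in subs] == [["c", "d", "e"], ["a", "b"]]

    def test_threshold_below_cutoff_rejected(self):
        net = build_network(["a"], [], tw_cutoff=0.3)
        with pytest.raises(ValueError):
            decompose(net, 0.1)


class TestNodeMetrics:
    def test_matches_brute_force(self, rng):
        coll, genes, table, profiles, net = make_net(rng)
        m = node_metrics(net, table, profiles)
        weights = table.weights()
        for g in genes:
            inc = [e for e in net.edges if g in e.key]
            assert m.loc[g, "degree"] == len(inc)
            assert m.loc[g, "sum_tw"] == pytest.approx(sum(e.tw for e in inc), abs=1e-12)
            expected_w = sum(
                weights[t] for t in profiles[g].associated_terms if t in weights
            )
            assert m.loc[g, "sum_weight"] == pytest.approx(expected_w, rel=1e-12)
            assert m.loc[g, "sum_tw"] <= m.loc[g, "degree"] + 1e-12

    def test_isolated_node_zero_degree(self, tiny_collection):
        genes = ["RPL7", "LSM10"]
        table = fisher_enrichment(genes, tiny_collection)
        profiles = build_profiles(tiny_collection, genes)
        net = build_network(genes, pairwise_edges(genes, profiles, table))
        m = node_metrics(net, table, profiles)
        assert m.loc["LSM10", "degree"] == 0
        assert m.loc["LSM10", "sum_tw"] == 0.0


class TestAttributeCorrelation:
    def test_perfect_correlations(self, rng):
        coll, genes, table, profiles, net = make_net(rng)
        m = node_metrics(net, table, profiles)
        m["node_attr"] = m["sum_tw"]
        r, _ = attribute_correlation(m, "sum_tw", "pearson")
        assert r == pytest.approx(1.0)
        m["node_attr"] = -m["sum_tw"]
        r, _ = attribute_correlation(m, "sum_tw", "pearson")
        assert r == pytest.approx(-1.0)

    def test_independent_noise_is_near_zero(self, rng):
        """Random attributes decorrelate from sum_tw for a large network."""
        rs = []
        for seed in range(8):
            local = np.random.default_rng(seed)
            coll, genes, table, profiles, net = make_net(rng, list_size=20)
            m = node_metrics(net, table, profiles)
            m["node_attr"] = local.normal(size=len(m))
            r, _ = attribute_correlation(m, "sum_tw", "spearman")
            rs.append(r)
        assert abs(np.mean(rs)) < 0.25

    def test_missing_or_constant_attrs_rejected(self, rng):
        _, _, table, profiles, net = make_net(rng)
        m = node_metrics(net, table, profiles)
        with pytest.raises(ValueError):
            attribute_correlation(m, "sum_tw")  # all attrs missing
        m["node_attr"] = 1.0
        with pytest.raises(ValueError):
            attribute_correlation(m, "sum_tw")


class TestConsensus:
    def test_single_list_equals_single_network(self, rng):
        coll, genes, table, profiles, net = make_net(rng)
        cn = build_consensus_network({"l1": genes}, coll)
        assert {e.key: e.tw for e in cn.edges} == {e.key: e.tw for e in net.edges}

    def test_duplicated_list_mean_log_mirrors_within(self, rng):
        coll, genes, _, _, net = make_net(rng)
        cn = build_consensus_network({"a": genes, "b": genes}, coll, method="mean_log")
        assert {e.key: e.tw for e in cn.edges} == {e.key: e.tw for e in net.edges}

    def test_two_list_fixture_matches_policy_oracle(self, rng):
        """Cross edges use the combined weights of the two lists involved;
        verified by direct recomputation."""
        from ontonet.enrichment import combine_pvalues

        coll, genes, _, _, _ = make_net(rng, list_size=14)
        la, lb = genes[:8], genes[6:]
        cn = build_consensus_network({"a": la, "b": lb}, coll, method="chisq")
        ta = fisher_enrichment(la, coll, list_id="a")
        tb = fisher_enrichment(lb, coll, list_id="b")
        profiles = build_profiles(coll, sorted(set(la) | set(lb)))
        combined = {}
        for tid in ta.term_ids() | tb.term_ids():
            pa = ta.rows[tid].p_value if tid in ta else 1.0
            pb = tb.rows[tid].p_value if tid in tb else 1.0
            combined[tid] = combine_pvalues([pa, pb], "chisq")[1]
        for e in cn.edges:
            in_a = e.gene_a in la and e.gene_b in la
            in_b = e.gene_a in lb and e.gene_b in lb
            if in_a:
                w = ta.weights()
            elif in_b:
                w = tb.weights()
            else:
                w = combined
            pa_terms = {t for t in profiles[e.gene_a].associated_terms if t in w}
            pb_terms = {t for t in profiles[e.gene_b].associated_terms if t in w}
            inter = sum(w[t] for t in sorted(pa_terms & pb_terms))
            union = sum(w[t] for t in sorted(pa_terms | pb_terms))
            assert e.tw == pytest.approx(inter / union, rel=1e-12)

    def test_node_identity_across_lists(self, rng):
        coll, genes, _, _, _ = make_net(rng, list_size=10)
        cn = build_consensus_network({"a": genes[:6], "b": genes[4:]}, coll)
        shared = set(genes[4:6])
        for g in shared:
            assert cn.nodes[g].node_type == 1  # lowest list index
            assert cn.nodes[g].list_ids == {"a", "b"}

    def test_too_many_lists_rejected(self, rng):
        coll, genes, _, _, _ = make_net(rng)
        lists = {f"l{i}": genes for i in range(6)}
        with pytest.raises(ValueError):
            build_consensus_network(lists, coll)


class TestLayoutAndExport:
    def test_layout_deterministic_under_seed(self, rng):
        _, _, _, _, net = make_net(rng)
        assert layout(net, seed=7) == layout(net, seed=7)

    def test_two_node_layout_finite(self):
        net = build_network(["a", "b"], [EdgeRecord("a", "b", 0.5, {"t": 1.0})])
        pos = layout(net, seed=1)
        d = np.hypot(*(np.array(pos["a"]) - np.array(pos["b"])))
        assert np.isfinite(d) and d > 0

    def test_high_tw_pairs_sit_closer_on_path(self):
        """On a path a-b-c with Tw(a,b) >> Tw(b,c), the strong pair is drawn
        closer, on average over seeds."""
        net = build_network(
            ["a", "b", "c"],
            [
                EdgeRecord("a", "b", 0.9, {"t": 1.0}),
                EdgeRecord("b", "c", 0.1, {"t": 1.0}),
            ],
        )
        closer = 0
        for seed in range(30):
            pos = layout(net, seed=seed)
            d_ab = np.hypot(*(np.array(pos["a"]) - np.array(pos["b"])))
            d_bc = np.hypot(*(np.array(pos["b"]) - np.array(pos["c"])))
            closer += d_ab < d_bc
        assert closer >= 20

    @pytest.mark.parametrize("fmt", ["graphml", "json"])
    def test_round_trip_losslessness(self, rng, tmp_path, fmt):
        coll, genes, table, profiles, _ = make_net(rng)
        edges = pairwise_edges(genes, profiles, table)
        attrs = {genes[0]: 1.5}
        net = build_network(
            genes, edges, node_attrs=attrs,
            list_ids={g: {"l1"} for g in genes},
            provenance={"collection": "test"},
        )
        p = tmp_path / f"net.{fmt}"
        export_network(net, p, fmt)
        back = import_network(p, fmt)
        assert back.nodes == net.nodes
        assert back.tw_cutoff == net.tw_cutoff
        assert {e.key: e.tw for e in back.edges} == {e.key: e.tw for e in net.edges}
        assert {e.key: dict(e.shared_terms) for e in back.edges} == {
            e.key: dict(e.shared_terms) for e in net.edges
        }

    def test_empty_network_exports_valid_files(self, tmp_path):
        net = build_network(["a", "b"], [])
        for fmt in ("graphml", "json", "edge_tsv"):
            p = tmp_path / f"empty.{fmt}"
            export_network(net, p, fmt)
            assert p.stat().st_size > 0
        assert import_network(tmp_path / "empty.graphml", "graphml").nodes == net.nodes

    def test_unknown_format_rejected(self, tmp_path):
        net = build_network(["a"], [])
        with pytest.raises(ValueError):
            export_network(net, tmp_path / "x", "gexf")
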