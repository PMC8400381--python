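import networkx as nx
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ralogic import integrate as I
from ralogic.netio import (
    NetworkNode,
    NodeKind,
    Origin,
    OverlayTable,
    Sign,
    SignedEdge,
    SignedNetwork,
)

from conftest import build_network


class TestNormalizeSymbol:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            (" Jun ", "JUN"),
            ("NFKB1@nucleus", "NFKB1"),
            ("il 6", "IL_6"),
            ("tnf@plasma membrane", "TNF"),
        ],
    )
    def test_examples(self, raw, expected):
        assert I.normalize_symbol(raw) == expected

    def test_empty_after_strip(self):
        with pytest.raises(I.IntegrateError):
            I.normalize_symbol("   ")

    @given(st.text(min_size=1, max_size=20))
    def test_idempotent(self, raw):
        try:
            once = I.normalize_symbol(raw)
        except I.IntegrateError:
            return
        assert I.normalize_symbol(once) == once


class TestExpandComplexes:
    def _complex_net(self):
        net = SignedNetwork()
        net.add_node(NetworkNode("AP1", "AP1", NodeKind.COMPLEX))
        net.add_edge(SignedEdge("AP1", "G", Sign.ACTIVATION))
        return net

    def test_members_wired_in(self):
        net = I.expand_complexes(self._complex_net(), {"AP1": ["JUN", "FOS"]})
        assert net.has_edge("JUN", "AP1", Sign.ACTIVATION)
        assert net.has_edge("FOS", "AP1", Sign.ACTIVATION)
        assert net.has_edge("AP1", "G", Sign.ACTIVATION)

    def test_empty_membership_identity(self):
        net = self._complex_net()
        assert I.expand_complexes(net, {}) == net

    def test_non_complex_key_rejected(self):
        net = self._complex_net()
        with pytest.raises(I.IntegrateError):
            I.expand_complexes(net, {"G": ["X"]})

    def test_node_count_delta(self):
        net = self._complex_net()
        net.add_node(NetworkNode("JUN", "JUN"))
        before = len(net.nodes)
        out = I.expand_complexes(net, {"AP1": ["JUN", "FOS"]})
        assert len(out.nodes) == before + 1  # only FOS is new

    def test_preexisting_edges_preserved(self):
        net = self._complex_net()
        out = I.expand_complexes(net, {"AP1": ["JUN"]})
        for edge in net.edges:
            assert out.has_edge(edge.source, edge.target, edge.sign)


class TestDeduplicate:
    def test_collapse(self):
        net = build_network(
            [("A", "ACTIVATION", "TNF_GENE"), ("A", "ACTIVATION", "TNF")]
        )
        net.add_node(NetworkNode("TNF_MRNA", "TNF_MRNA"))
        out = I.deduplicate_entities(net, [{"TNF_GENE", "TNF_MRNA", "TNF"}])
        assert out.node_ids() == {"A", "TNF"}
        assert len(out.edges) == 1

    def test_no_groups_identity(self):
        net = build_network([("A", "ACTIVATION", "B")])
        assert I.deduplicate_entities(net, []) == net

    def test_unknown_id_rejected(self):
        net = build_network([("A", "ACTIVATION", "B")])
        with pytest.raises(I.IntegrateError):
            I.deduplicate_entities(net, [{"A", "NOPE"}])

    def test_overlapping_groups_rejected(self):
        net = build_network([("A", "ACTIVATION", "B"), ("B", "ACTIVATION", "C")])
        with pytest.raises(I.IntegrateError):
            I.deduplicate_entities(net, [{"A", "B"}, {"B", "C"}])

    def test_self_edges_from_collapse_dropped(self):
        net = build_network([("X1", "ACTIVATION", "X2")])
        out = I.deduplicate_entities(net, [{"X1", "X2"}])
        assert out.edges == []

    @given(st.data())
    def test_no_dangling_alias(self, data):
        names = [f"N{i}" for i in range(8)]
        edges = data.draw(
            st.lists(
                st.tuples(st.sampled_from(names), st.just("ACTIVATION"), st.sampled_from(names)),
                min_size=1, max_size=15,
            )
        )
        net = build_network(edges)
        ids = sorted(net.node_ids())
        if len(ids) < 2:
            return
        group = set(data.draw(st.lists(st.sampled_from(ids), min_size=2, max_size=4, unique=True)))
        out = I.deduplicate_entities(net, [group])
        removed = group - {min(group)}
        for edge in out.edges:
            assert edge.source not in removed
            assert edge.target not in removed


class TestMatchTfs:
    def test_paper_fixture_intersection(self):
        coreg_tfs = {
            "ETS1", "FOS", "JUN", "JUND", "NFKBIA", "TNFAIP3",
            "EEF1A1", "IRF1", "MNDA", "PTMA", "BCL6", "MXD1", "DAZAP2",
            "FOSB", "HCLS1", "TRIM22", "KLF6", "ZFP36", "NR4A2",
        }
        assert len(coreg_tfs) == 19
        map_nodes = {"ETS1", "FOS", "JUN", "JUND", "NFKBIA", "TNFAIP3", "TNF", "IL6"}
        matched = I.match_tfs(coreg_tfs, map_nodes)
        assert matched == {"ETS1", "FOS", "JUN", "JUND", "NFKBIA", "TNFAIP3"}
        assert len(matched) == 6

    def test_disjoint(self):
        assert I.match_tfs({"A"}, {"B"}) == set()

    @given(
        st.sets(st.sampled_from("ABCDEFG"), max_size=7),
        st.sets(st.sampled_from("ABCDEFG"), max_size=7),
    )
    def test_bounded_by_smaller_set(self, a, b):
        assert len(I.match_tfs(a, b)) <= min(len(a), len(b))


class TestMerge:
    def test_basic(self):
        coreg = SignedNetwork()
        coreg.add_node(NetworkNode("JUN", "JUN", NodeKind.TF, Origin.COREG))
        coreg.add_edge(SignedEdge("JUN", "G1", Sign.ACTIVATION))
        signalling = build_network([("TNF", "ACTIVATION", "JUN")])
        merged, summary = I.merge_networks(coreg, signalling)
        assert len(merged.nodes) == 3
        assert len(merged.edges) == 2
        assert merged.nodes["JUN"].origin is Origin.BOTH
        assert summary.n_shared_nodes == 1

    def test_merge_with_empty_identity_on_edges(self):
        net = build_network([("A", "ACTIVATION", "B")])
        merged, _ = I.merge_networks(net, SignedNetwork())
        assert {e.key() for e in merged.edges} == {e.key() for e in net.edges}
        assert merged.node_ids() == net.node_ids()

    @given(st.data())
    def test_commutative_up_to_origin(self, data):
        names = [f"N{i}" for i in range(6)]
        def draw_net():
            edges = data.draw(
                st.lists(
                    st.tuples(
                        st.sampled_from(names),
                        st.sampled_from(["ACTIVATION", "INHIBITION"]),
                        st.sampled_from(names),
                    ),
                    min_size=1, max_size=10,
                )
            )
            return build_network(edges)
        a, b = draw_net(), draw_net()
        ab, _ = I.merge_networks(a, b)
        ba, _ = I.merge_networks(b, a)
        assert {e.key() for e in ab.edges} == {e.key() for e in ba.edges}
        assert ab.node_ids() == ba.node_ids()

    @given(st.data())
    def test_never_loses_an_edge(self, data):
        names = [f"N{i}" for i in range(6)]
        edges = data.draw(
            st.lists(
                st.tuples(st.sampled_from(names), st.just("ACTIVATION"), st.sampled_from(names)),
                min_size=1, max_size=10,
            )
        )
        a = build_network(edges[: len(edges) // 2 + 1])
        b = build_network(edges[len(edges) // 2:] or edges[:1])
        merged, _ = I.merge_networks(a, b)
        for net in (a, b):
            for edge in net.edges:
                assert merged.has_edge(edge.source, edge.target, edge.sign)


class TestExtract:
    def test_upstream_chain(self, chain_net):
        sub = I.extract_upstream(chain_net, {"C"})
        assert sub.node_ids() == {"A", "B", "C"}

    def test_upstream_seed_without_regulators(self, chain_net):
        sub = I.extract_upstream(chain_net, {"A"})
        assert sub.node_ids() == {"A"}

    def test_unknown_seed(self, chain_net):
        with pytest.raises(I.IntegrateError, match="NOPE"):
            I.extract_upstream(chain_net, {"NOPE"})

    def test_induced_edges_have_both_endpoints(self, chain_net):
        sub = I.extract_upstream(chain_net, {"B"})
        for edge in sub.edges:
            assert {edge.source, edge.target} <= sub.node_ids()

    @given(st.data())
    def test_upstream_matches_networkx_ancestors(self, data):
        # oracle: reverse reachability via networkx on a generated DAG
        n = data.draw(st.integers(min_value=3, max_value=10))
        names = [f"N{i}" for i in range(n)]
        edges = data.draw(
            st.lists(
                st.tuples(st.integers(0, n - 1), st.integers(0, n - 1)).filter(
                    lambda t: t[0] < t[1]
                ),
                min_size=1,
                max_size=20,
            )
        )
        net = build_network([(names[a], "ACTIVATION", names[b]) for a, b in edges])
        g = nx.DiGraph([(names[a], names[b]) for a, b in edges])
        seed = data.draw(st.sampled_from(sorted(net.node_ids())))
        expected = nx.ancestors(g, seed) | {seed} if seed in g else {seed}
        assert I.extract_upstream(net, {seed}).node_ids() == expected

    def test_downstream_tf_absorbing(self):
        net = build_network(
            [
                ("TNF", "ACTIVATION", "K"),
                ("K", "ACTIVATION", "JUN"),
                ("JUN", "ACTIVATION", "G1"),
            ]
        )
        sub = I.extract_downstream_to_first_tf(net, {"TNF"}, {"JUN"})
        assert sub.node_ids() == {"TNF", "K", "JUN"}

    def test_downstream_seed_is_tf(self):
        net = build_network([("JUN", "ACTIVATION", "G1")])
        sub = I.extract_downstream_to_first_tf(net, {"JUN"}, {"JUN"})
        assert sub.node_ids() == {"JUN"}

    @given(st.data())
    def test_downstream_nodes_reachable_without_crossing_tfs(self, data):
        n = data.draw(st.integers(min_value=3, max_value=10))
        names = [f"N{i}" for i in range(n)]
        edges = data.draw(
            st.lists(
                st.tuples(st.integers(0, n - 1), st.integers(0, n - 1)).filter(
                    lambda t: t[0] != t[1]
                ),
                min_size=1,
                max_size=20,
            )
        )
        net = build_network([(names[a], "ACTIVATION", names[b]) for a, b in edges])
        ids = sorted(net.node_ids())
        seed = data.draw(st.sampled_from(ids))
        tfs = set(data.draw(st.lists(st.sampled_from(ids), max_size=3, unique=True)))
        sub = I.extract_downstream_to_first_tf(net, {seed}, tfs)
        # oracle: BFS on the raw edge list that refuses to expand TFs
        reach = {seed}
        frontier = [seed] if seed not in tfs else []
        while frontier:
            node = frontier.pop()
            for a, b in edges:
                if names[a] == node and names[b] not in reach:
                    reach.add(names[b])
                    if names[b] not in tfs:
                        frontier.append(names[b])
        assert sub.node_ids() == reach


class TestThresholds:
    def _deg(self, fdrs):
        rows = pd.DataFrame(
            {"gene": [f"G{i}" for i in range(len(fdrs))], "log2fc": 1.0, "fdr": fdrs}
        )
        return OverlayTable(kind="DEG", rows=rows)

    def test_strict_fdr(self):
        assert I.select_degs(self._deg([0.05, 0.1, 0.2]), 0.1) == {"G0"}

    def test_empty_table(self):
        assert I.select_degs(self._deg([]), 0.1) == set()

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_in_threshold(self, fdrs):
        table = self._deg(fdrs)
        low = I.select_degs(table, 0.05)
        high = I.select_degs(table, 0.5)
        assert low <= high

    def _variants(self, pairs):
        rows = pd.DataFrame(
            {
                "variant": [f"V{i}" for i in range(len(pairs))],
                "gene": [f"G{i}" for i in range(len(pairs))],
                "vda": [p[0] for p in pairs],
                "ei": [p[1] for p in pairs],
            }
        )
        return OverlayTable(kind="VARIANT", rows=rows)

    def test_variant_and_filter(self):
        kept, genes = I.filter_variants(self._variants([(0.8, 0.9), (0.8, 0.6), (0.6, 0.9)]))
        assert len(kept) == 1
        assert genes == {"G0"}

    def test_threshold_inclusive(self):
        kept, _ = I.filter_variants(self._variants([(0.7, 0.7), (0.7, 0.7)]))
        assert len(kept) == 2

    def test_gene_set_bounded(self):
        kept, genes = I.filter_variants(self._variants([(0.9, 0.9)] * 5))
        assert len(genes) <= len(kept)


class TestProjectOverlay:
    def test_partial_match_reported(self, chain_net):
        overlay = I.project_overlay(chain_net, {"DEG_TREATMENT": {"A", "NOTANODE"}})
        assert overlay.markers["DEG_TREATMENT"] == {"A"}
        assert overlay.report["DEG_TREATMENT"] == {"matched": 1, "unmatched": 1}

    def test_empty_markers(self, chain_net):
        overlay = I.project_overlay(chain_net, {})
        assert overlay.markers == {}

    def test_idempotent(self, chain_net):
        first = I.project_overlay(chain_net, {"VARIANT_CARRIER": {"A", "B", "ZZ"}})
        second = I.project_overlay(chain_net, first.markers)
        assert second.markers == first.markers
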