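"""Repurposing network construction, knockout masks, ranking and export."""

import json
import math

import networkx as nx
import numpy as np
import pytest

import rebrain as rb


def brute_force_distances(pset, ref_id, mask=None):
    ref = pset.profile(ref_id).vector(mask)
    return {
        did: float(np.sqrt(np.sum((pset.profile(did).vector(mask) - ref) ** 2)))
        for did in pset
    }


class TestQueryValidation:
    def test_unknown_reference_is_named(self, small_catalog):
        query = rb.NetworkQuery(reference_id="nope")
        with pytest.raises(KeyError, match="nope"):
            rb.build_query_network(small_catalog, query)

    def test_default_parameters(self):
        q = rb.NetworkQuery(reference_id="X")
        assert q.top_k == 9
        assert q.mw_max == 500.0
        assert math.isinf(q.distance_max)
        assert q.mask == frozenset(rb.COMPONENT_IDS)
        assert q.edge_mode == "star"

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            rb.NetworkQuery(reference_id="X", mask=frozenset())


class TestKnockout:
    def test_knockout_removes_components(self):
        q = rb.NetworkQuery(reference_id="X")
        q2 = rb.apply_knockout(q, {"COX2"})
        assert len(q2.mask) == 14 and "COX2" not in q2.mask

    def test_empty_knockout_is_identity(self):
        q = rb.NetworkQuery(reference_id="X")
        assert rb.apply_knockout(q, set()) == q

    def test_unknown_component_rejected(self):
        with pytest.raises(KeyError, match="WNT"):
            rb.apply_knockout(rb.NetworkQuery(reference_id="X"), {"WNT"})

    def test_knocking_out_all_fifteen_rejected(self):
        with pytest.raises(ValueError):
            rb.apply_knockout(rb.NetworkQuery(reference_id="X"), set(rb.COMPONENT_IDS))

    def test_knockin_restores_component(self):
        q = rb.apply_knockout(rb.NetworkQuery(reference_id="X"), {"COX2", "TERT"})
        q2 = rb.apply_knockin(q, {"COX2"})
        assert "COX2" in q2.mask and "TERT" not in q2.mask

    def test_knockout_of_all_differing_components_collapses_distance(self, toy_profile_set):
        # A and B differ everywhere except the shared midpoint component
        a = toy_profile_set.profile("A").vector()
        b = toy_profile_set.profile("B").vector()
        same = {cid for cid, va, vb in zip(rb.COMPONENT_IDS, a, b) if va == vb}
        assert same  # the midpoint component
        assert rb.euclidean_distance(a, b, same) == 0.0


class TestBuildNetwork:
    def test_distance_zero_threshold_keeps_only_duplicates(self, toy_profile_set):
        pset = rb.ProfileSet()
        for did in toy_profile_set:
            pset.add(toy_profile_set.record(did), toy_profile_set.profile(did))
        pset.add(rb.DrugRecord("A2", "twin", 150.0),
                 rb.MolecularProfile.from_vector("A2", toy_profile_set.profile("A").vector()))
        net = rb.build_query_network(pset, rb.NetworkQuery(reference_id="A", distance_max=0.0))
        assert set(net.node_ids) == {"A", "A2"}

    def test_node_set_matches_brute_force_distances(self, small_catalog):
        ref = small_catalog.ids()[0]
        dists = brute_force_distances(small_catalog, ref)
        cutoff = sorted(dists.values())[len(dists) // 2]
        query = rb.NetworkQuery(reference_id=ref, distance_max=cutoff, mw_max=math.inf)
        net = rb.build_query_network(small_catalog, query)
        expected = {d for d, v in dists.items() if v <= cutoff} | {ref}
        assert set(net.node_ids) == expected

    def test_reference_survives_its_own_mw_filter(self, small_catalog):
        heavy = max(small_catalog.ids(), key=lambda d: small_catalog.record(d).molecular_weight)
        assert small_catalog.record(heavy).molecular_weight > 500
        net = rb.build_query_network(small_catalog, rb.NetworkQuery(reference_id=heavy))
        assert heavy in net.node_ids

    def test_mw_filter_excludes_heavy_candidates(self, small_catalog):
        ref = min(small_catalog.ids(), key=lambda d: small_catalog.record(d).molecular_weight)
        net = rb.build_query_network(small_catalog, rb.NetworkQuery(reference_id=ref, mw_max=500))
        for did in net.node_ids:
            if did != ref:
                assert small_catalog.record(did).molecular_weight <= 500

    def test_star_edges_connect_reference_to_every_candidate(self, small_catalog):
        ref = small_catalog.ids()[0]
        net = rb.build_query_network(
            small_catalog, rb.NetworkQuery(reference_id=ref, mw_max=math.inf)
        )
        assert net.graph.number_of_edges() == len(net.node_ids) - 1
        assert all(ref in edge for edge in net.graph.edges)

    def test_mutual_mode_adds_candidate_pair_edges_within_threshold(self, small_catalog):
        ref = small_catalog.ids()[0]
        query = rb.NetworkQuery(reference_id=ref, distance_max=2.0, mw_max=math.inf,
                                edge_mode="mutual")
        net = rb.build_query_network(small_catalog, query)
        for a, b, data in net.graph.edges(data=True):
            va = small_catalog.profile(a).vector()
            vb = small_catalog.profile(b).vector()
            assert data["distance"] == pytest.approx(rb.euclidean_distance(va, vb))
            assert data["distance"] <= 2.0

    def test_knockout_monotonicity_shrinking_mask_never_shrinks_nodes(self, small_catalog):
        ref = small_catalog.ids()[0]
        query = rb.NetworkQuery(reference_id=ref, distance_max=1.0, mw_max=math.inf)
        full_nodes = set(rb.build_query_network(small_catalog, query).node_ids)
        smaller = rb.apply_knockout(query, {"COX2", "TERT", "CDK1", "CDK2", "CDK3"})
        sub_nodes = set(rb.build_query_network(small_catalog, smaller).node_ids)
        assert full_nodes <= sub_nodes


class TestPrioritize:
    def test_matches_exhaustive_sort(self, small_catalog):
        ref = small_catalog.ids()[3]
        query = rb.NetworkQuery(reference_id=ref, mw_max=math.inf, top_k=9)
        ranked = rb.prioritize(small_catalog, query)
        dists = brute_force_distances(small_catalog, ref)
        expected = sorted(
            ((d, small_catalog.record(did).name.lower(), did)
             for did, d in dists.items() if did != ref)
        )[:9]
        assert [r.drug_id for r in ranked.rows] == [did for _, _, did in expected]
        assert [r.distance for r in ranked.rows] == pytest.approx([d for d, _, _ in expected])

    def test_full_ordering_equals_brute_force_at_top_k_n_minus_one(self, small_catalog):
        ref = small_catalog.ids()[0]
        n = len(small_catalog)
        query = rb.NetworkQuery(reference_id=ref, mw_max=math.inf, top_k=n - 1)
        ranked = rb.prioritize(small_catalog, query)
        dists = [r.distance for r in ranked.rows]
        assert dists == sorted(dists)
        assert len(ranked) == n - 1

    def test_reference_never_in_its_own_list(self, small_catalog):
        for ref in small_catalog.ids()[:3]:
            query = rb.NetworkQuery(reference_id=ref, mw_max=math.inf, top_k=11)
            assert ref not in [r.drug_id for r in rb.prioritize(small_catalog, query).rows]

    def test_catalog_of_only_reference_yields_empty_list(self):
        pset = rb.make_mock_catalog(1, seed=0)
        query = rb.NetworkQuery(reference_id=pset.ids()[0], mw_max=math.inf)
        assert len(rb.prioritize(pset, query)) == 0

    def test_ties_broken_by_name_then_id(self):
        pset = rb.ProfileSet()
        vec = np.linspace(0, 1, 15)
        pset.add(rb.DrugRecord("R", "ref", 100.0), rb.MolecularProfile.from_vector("R", vec))
        for did, name in [("Z1", "beta"), ("Z2", "alpha"), ("Z3", "alpha")]:
            pset.add(rb.DrugRecord(did, name, 100.0), rb.MolecularProfile.from_vector(did, vec))
        ranked = rb.prioritize(pset, rb.NetworkQuery(reference_id="R"))
        assert [r.drug_id for r in ranked.rows] == ["Z2", "Z3", "Z1"]

    def test_deterministic_pure_function(self, small_catalog):
        ref = small_catalog.ids()[0]
        query = rb.NetworkQuery(reference_id=ref, mw_max=math.inf)
        a = rb.prioritize(small_catalog, query)
        b = rb.prioritize(small_catalog, query)
        assert a == b

    def test_rows_carry_significance_at_0p6(self, small_catalog):
        ref = small_catalog.ids()[0]
        ranked = rb.prioritize(small_catalog, rb.NetworkQuery(reference_id=ref, mw_max=math.inf))
        for row in ranked.rows:
            assert row.significant is (row.r2 > 0.6)


class TestExport:
    def test_graphml_round_trip_preserves_nodes_and_distances(self, small_catalog, tmp_path):
        ref = small_catalog.ids()[0]
        net = rb.build_query_network(
            small_catalog, rb.NetworkQuery(reference_id=ref, mw_max=math.inf)
        )
        path = rb.export_network(net, "graphml", tmp_path / "net.graphml")
        loaded = nx.read_graphml(path)
        assert set(loaded.nodes) == set(net.node_ids)
        for a, b, data in loaded.edges(data=True):
            va = small_catalog.profile(a).vector()
            vb = small_catalog.profile(b).vector()
            assert float(data["distance"]) == pytest.approx(rb.euclidean_distance(va, vb))

    def test_json_node_link_export(self, small_catalog, tmp_path):
        ref = small_catalog.ids()[0]
        net = rb.build_query_network(
            small_catalog, rb.NetworkQuery(reference_id=ref, mw_max=math.inf)
        )
        path = rb.export_network(net, "json_node_link", tmp_path / "net.json")
        payload = json.loads(path.read_text())
        assert {n["id"] for n in payload["nodes"]} == set(net.node_ids)

    def test_single_node_network_exports(self, tmp_path):
        pset = rb.make_mock_catalog(1, seed=0)
        net = rb.build_query_network(
            pset, rb.NetworkQuery(reference_id=pset.ids()[0], mw_max=math.inf)
        )
        path = rb.export_network(net, "graphml", tmp_path / "one.graphml")
        assert len(nx.read_graphml(path).nodes) == 1

    def test_unknown_format_rejected(self, small_catalog, tmp_path):
        net = rb.build_query_network(
            small_catalog,
            rb.NetworkQuery(reference_id=small_catalog.ids()[0], mw_max=math.inf),
        )
        with pytest.raises(ValueError, match="format"):
            rb.export_network(net, "dot", tmp_path / "net.dot")
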