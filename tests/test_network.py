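"""Flow network construction, disparity filter, MST, backbone."""

import itertools

import networkx as nx
import pytest

from readmitnet.cohort import CohortConfig, build_cohort
from readmitnet.network import (
    build_flow_network,
    disparity_filter,
    disparity_significance,
    export_edge_list,
    extract_backbone,
    maximum_spanning_tree,
    write_graphml,
)

from conftest import make_records


def _combos(rows):
    import pandas as pd

    return pd.DataFrame(rows, columns=["d1", "d2", "sex", "n_cases"])


class TestBuildFlowNetwork:
    def test_single_patient_unit_flow(self):
        recs = make_records(
            [
                {"sex": "m", "index_dx": {"I25"}, "readmitted": True,
                 "readmission_main_dx": "I21", "readmission_day": 200,
                 "internal medicine": True}
            ]
        )
        combos = _combos([("I25", "I21", "m", 1)])
        G = build_flow_network(recs, combos)
        assert set(G.edges) == {("I25", "internal medicine"), ("internal medicine", "I21")}
        for _u, _v, e in G.edges(data=True):
            assert e["weight"] == 1
        assert G.nodes["I25"]["type"] == "diagnosis"
        assert G.nodes["internal medicine"]["type"] == "specialty"

    def test_no_contacts_gives_empty_edge_set(self):
        recs = make_records(
            [
                {"sex": "m", "index_dx": {"I25"}, "readmitted": True,
                 "readmission_main_dx": "I21", "readmission_day": 200}
            ]
        )
        combos = _combos([("I25", "I21", "m", 1)])
        assert build_flow_network(recs, combos).number_of_edges() == 0

    def test_sex_ratio_contract(self):
        rows = []
        for i in range(30):
            rows.append({"sex": "m", "index_dx": {"I25"}, "readmitted": True,
                         "readmission_main_dx": "I21", "readmission_day": 200,
                         "internal medicine": True})
        for i in range(10):
            rows.append({"sex": "f", "index_dx": {"I25"}, "readmitted": True,
                         "readmission_main_dx": "I21", "readmission_day": 200,
                         "internal medicine": True})
        recs = make_records(rows)
        recs["patient_id"] = range(len(recs))
        combos = _combos([("I25", "I21", "m", 30), ("I25", "I21", "f", 10)])
        G = build_flow_network(recs, combos)
        e = G["I25"]["internal medicine"]
        assert e["weight"] == 40 and e["sex_ratio"] == pytest.approx(3.0)
        assert e["sex_ratio_defined"]

    def test_all_male_link_gets_inf_sentinel(self):
        recs = make_records(
            [
                {"sex": "m", "index_dx": {"I25"}, "readmitted": True,
                 "readmission_main_dx": "I21", "readmission_day": 200,
                 "internal medicine": True}
            ]
        )
        combos = _combos([("I25", "I21", "m", 1)])
        e = build_flow_network(recs, combos)["I25"]["internal medicine"]
        assert e["sex_ratio"] == float("inf") and not e["sex_ratio_defined"]


def _star(weights, center="hub"):
    G = nx.DiGraph()
    for i, w in enumerate(weights):
        G.add_edge(center, f"leaf{i}", weight=w)
    return G


class TestDisparityFilter:
    def test_hand_evaluated_star(self):
        """Hub of degree 3 with weights (6, 3, 1): the strongest edge has
        p = 0.6 so alpha = (1 - 0.6)^2 = 0.16."""
        G = _star([6, 3, 1])
        alpha = disparity_significance(G)
        assert alpha[("hub", "leaf0")] == pytest.approx(0.16)
        assert alpha[("hub", "leaf1")] == pytest.approx(0.7**2)
        assert alpha[("hub", "leaf2")] == pytest.approx(0.9**2)

    def test_equal_weight_pair_is_filtered_at_005(self):
        G = _star([5, 5])
        alpha = disparity_significance(G)
        assert all(a == pytest.approx(0.5) for a in alpha.values())
        assert disparity_filter(G, 0.05) == set()

    def test_level_one_retains_everything_below_one(self):
        G = _star([6, 3, 1])
        assert disparity_filter(G, 1.0) == set(G.edges)

    def test_uniform_star_retains_nothing_through_hub(self):
        G = _star([2, 2, 2, 2])
        # each edge: hub side (1 - 1/4)^3 ~ 0.42; leaf side degree 1 -> 1.0
        assert disparity_filter(G, 0.4) == set()

    def test_degree_one_endpoints_never_pass_alone(self):
        G = nx.DiGraph()
        G.add_edge("a", "b", weight=100)
        assert disparity_significance(G)[("a", "b")] == 1.0
        assert disparity_filter(G, 0.9999) == set()

    def test_invariant_under_uniform_rescaling(self):
        G1 = _star([6, 3, 1])
        G2 = _star([60, 30, 10])
        a1, a2 = disparity_significance(G1), disparity_significance(G2)
        for e in a1:
            assert a1[e] == pytest.approx(a2[e])

    def test_alpha_strictly_decreasing_in_weight(self):
        alpha = disparity_significance(_star([5, 3, 2, 1]))
        ordered = [alpha[("hub", f"leaf{i}")] for i in range(4)]
        assert ordered == sorted(ordered)


class TestMaximumSpanningTree:
    def test_triangle_keeps_two_heaviest(self):
        G = nx.DiGraph()
        G.add_edge("a", "b", weight=3)
        G.add_edge("b", "c", weight=2)
        G.add_edge("c", "a", weight=1)
        assert maximum_spanning_tree(G) == {("a", "b"), ("b", "c")}

    def test_tree_input_returned_unchanged(self):
        G = nx.DiGraph()
        G.add_edge("a", "b", weight=1)
        G.add_edge("b", "c", weight=5)
        G.add_edge("b", "d", weight=2)
        assert maximum_spanning_tree(G) == set(G.edges)

    def test_equal_weight_tie_breaks_lexicographically(self):
        G = nx.DiGraph()
        G.add_edge("a", "b", weight=1)
        G.add_edge("a", "c", weight=2)
        G.add_edge("b", "c", weight=2)  # same weight: ('a','c') sorts first
        assert maximum_spanning_tree(G) == {("a", "c"), ("a", "b")} or maximum_spanning_tree(
            G
        ) == {("a", "c"), ("b", "c")}
        # deterministic across calls
        assert maximum_spanning_tree(G) == maximum_spanning_tree(G)

    def test_edge_count_matches_components(self):
        G = nx.DiGraph()
        G.add_edge("a", "b", weight=1)
        G.add_edge("b", "c", weight=1)
        G.add_edge("x", "y", weight=1)
        mst = maximum_spanning_tree(G)
        n_components = nx.number_connected_components(G.to_undirected())
        assert len(mst) == G.number_of_nodes() - n_components


class TestBackbone:
    def test_no_disparity_edges_gives_mst_exactly(self):
        G = _star([2, 2])  # all alpha = 0.5, nothing passes at 0.05
        bb = extract_backbone(G, 0.05)
        assert set(bb.edges) == maximum_spanning_tree(G)
        assert all(p == "mst" for p in bb.edges.values())

    def test_level_one_keeps_full_edge_set(self):
        G = _star([6, 3, 1])
        bb = extract_backbone(G, 1.0)
        assert set(bb.edges) == set(G.edges)

    def test_star_plus_significant_chord(self):
        """A dominant chord between two leaves passes the disparity filter
        and joins the star's MST in the backbone."""
        G = _star([10, 10, 10, 10])
        G.add_edge("leaf0", "leaf1", weight=200)
        bb = extract_backbone(G, 0.05)
        assert ("leaf0", "leaf1") in bb.edges
        mst = maximum_spanning_tree(G)
        assert mst <= set(bb.edges)
        # every original node stays covered
        covered = {n for e in bb.edges for n in e}
        assert covered == set(G.nodes)

    def test_intersection_mode_is_subset_of_union(self):
        G = _star([8, 4, 2, 1])
        union = extract_backbone(G, 0.3, mode="union")
        inter = extract_backbone(G, 0.3, mode="intersection")
        assert set(inter.edges) <= set(union.edges)

    def test_backbone_edge_count_lower_bound(self, small_world):
        _sim, ds, cfg = small_world
        records, combos, _ = build_cohort(ds, cfg)
        G = build_flow_network(records, combos)
        bb = extract_backbone(G, 0.05)
        n_comp = nx.number_connected_components(G.to_undirected())
        assert len(bb.edges) >= G.number_of_nodes() - n_comp
        assert set(bb.edges) <= set(G.edges)


def test_flow_conservation_against_brute_force(small_world):
    """Total d1 -> s flow out of a diagnosis equals the number of
    (readmitted, contacted) patient-combination incidences counted by an
    independent scan of the cohort records."""
    _sim, ds, cfg = small_world
    records, combos, _ = build_cohort(ds, cfg)
    G = build_flow_network(records, combos)
    combo_keys = set(map(tuple, combos[["d1", "d2", "sex"]].to_numpy()))
    specialties = [c[len("contact::"):] for c in records.columns if c.startswith("contact::")]

    for d1 in {k[0] for k in combo_keys}:
        expected = 0
        for rec_d in records[records["readmitted"]].to_dict("records"):
            if d1 not in rec_d["index_dx"]:
                continue
            if (d1, rec_d["readmission_main_dx"], rec_d["sex"]) not in combo_keys:
                continue
            expected += sum(bool(rec_d["contact::" + s]) for s in specialties)
        got = sum(e["weight"] for _u, _v, e in G.out_edges(d1, data=True))
        assert got == expected


def test_exports_round_trip(tmp_path, small_world):
    _sim, ds, cfg = small_world
    records, combos, _ = build_cohort(ds, cfg)
    G = build_flow_network(records, combos)
    bb = extract_backbone(G, 0.05)
    table = export_edge_list(G, bb)
    assert set(table.columns) >= {"source", "target", "weight", "sex_ratio", "provenance"}
    assert len(table) == len(bb.edges)
    path = tmp_path / "net.graphml"
    write_graphml(G, path)
    H = nx.read_graphml(path)
    assert H.number_of_edges() == G.number_of_edges()
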