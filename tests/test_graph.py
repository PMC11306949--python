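import math

import numpy as np
import pandas as pd
import pytest

from aagraph.attributes import derive_attributes, compute_reference_ranges
from aagraph.cohort import CohortSpec, Criterion, assign_cohorts
from aagraph.config import GraphConfig
from aagraph.export import export_json
from aagraph.graph import (
    BuildError,
    assign_distinction_label,
    assign_edge_type,
    assign_frequency_label,
    build_graph,
    edge_statistics,
    node_statistics,
    share_comparison,
)
from aagraph.simulate import simulate_cohort

from conftest import make_table, small_simulation_spec, table_to_rows
from _oracle import oracle_graph


def _incidence_from_statuses(disease, control):
    """Build a 1-attribute table from explicit member/non_member/missing lists."""
    flag = []
    for status in disease + control:
        flag.append({"member": "yes", "non_member": "no", "missing": None}[status])
    group = ["d"] * len(disease) + ["c"] * len(control)
    table = make_table(
        {"attr": flag, "grp": group}, {"attr": "binary", "grp": "binary"}
    )
    assignment = assign_cohorts(
        table, CohortSpec(criteria=[Criterion("grp", "equals", "d")])
    )
    _, inc = derive_attributes(table, {})
    return table, inc, assignment


class TestNodeStatistics:
    def test_worked_example(self):
        # disease [member, member, non_member, missing],
        # control [member, non_member, non_member, non_member, missing]
        _, inc, assignment = _incidence_from_statuses(
            ["member", "member", "non_member", "missing"],
            ["member", "non_member", "non_member", "non_member", "missing"],
        )
        stats = node_statistics(inc, assignment, inc.attribute("attr=yes"))
        assert (stats.c_d, stats.n_d) == (2, 3)
        assert stats.rel_total_d == 2 / 4
        assert stats.p_d == 2 / 3
        assert (stats.c_c, stats.n_c) == (1, 4)
        assert stats.rel_total_c == 1 / 5
        assert stats.p_c == 1 / 4
        assert stats.delta == pytest.approx(0.4167, abs=5e-5)
        assert stats.gamma == pytest.approx(2.667, abs=5e-4)
        assert stats.direction == "disease_higher"

    def test_saturated_attribute(self):
        _, inc, assignment = _incidence_from_statuses(
            ["member", "member"], ["member", "member", "member"]
        )
        stats = node_statistics(inc, assignment, inc.attribute("attr=yes"))
        assert stats.p_d == stats.p_c == 1.0
        assert stats.delta == 0.0
        assert stats.gamma == 1.0
        assert stats.direction == "equal"
        assert stats.distinction_label == "unrelated"

    def test_no_missing_total_equals_attribute_share(self):
        _, inc, assignment = _incidence_from_statuses(
            ["member", "non_member"], ["member", "non_member", "non_member"]
        )
        stats = node_statistics(inc, assignment, inc.attribute("attr=yes"))
        assert stats.rel_total_d == stats.p_d
        assert stats.rel_total_c == stats.p_c

    def test_rel_total_bounded_by_attribute_share(self):
        _, inc, assignment = _incidence_from_statuses(
            ["member", "missing", "non_member"], ["member", "missing"]
        )
        stats = node_statistics(inc, assignment, inc.attribute("attr=yes"))
        assert stats.rel_total_d <= stats.p_d
        assert stats.rel_total_c <= stats.p_c

    def test_group_without_valid_values_unlabelled(self):
        _, inc, assignment = _incidence_from_statuses(
            ["missing", "missing"], ["member", "non_member"]
        )
        with pytest.warns(UserWarning, match="excluded"):
            stats = node_statistics(inc, assignment, inc.attribute("attr=yes"))
        assert stats.p_d is None
        assert stats.frequency_label is None
        assert stats.distinction_label is None


class TestFrequencyLabel:
    @pytest.mark.parametrize(
        "p,label",
        [
            (0.5, "highly_frequent"),
            (0.1, "frequent"),
            (0.09, "infrequent"),
            (1.0, "highly_frequent"),
            (0.49999, "frequent"),
            (0.0, "infrequent"),
        ],
    )
    def test_thresholds(self, p, label):
        assert assign_frequency_label(p) == label

    @pytest.mark.parametrize("p", [-0.1, 1.1, math.nan])
    def test_out_of_range(self, p):
        with pytest.raises(ValueError):
            assign_frequency_label(p)


class TestDistinctionLabel:
    def test_printed_low_cholesterol_shares(self):
        assert assign_distinction_label(0.163, 0.055) == "highly_related"

    def test_printed_high_cholesterol_shares(self):
        assert assign_distinction_label(0.473, 0.612) == "inverse"

    def test_equal_shares_unrelated(self):
        assert assign_distinction_label(0.3, 0.3) == "unrelated"

    def test_delta_exactly_at_high_threshold(self):
        # delta = 0.2 meets the >= 0.2 rule even though gamma ~ 1.667 < 2
        assert assign_distinction_label(0.5, 0.3) == "highly_related"

    def test_direction_flips_label_family(self):
        assert assign_distinction_label(0.055, 0.163) == "highly_inverse"
        assert assign_distinction_label(0.3, 0.45) == "inverse"
        assert assign_distinction_label(0.45, 0.3) == "related"

    def test_zero_vs_positive_share_exceeds_quotient(self):
        assert assign_distinction_label(0.05, 0.0) == "highly_related"
        assert assign_distinction_label(0.0, 0.05) == "highly_inverse"

    def test_both_zero_unrelated(self):
        assert assign_distinction_label(0.0, 0.0) == "unrelated"

    def test_share_comparison_conventions(self):
        assert share_comparison(0.4, 0.2) == (pytest.approx(0.2), 2.0)
        assert share_comparison(0.0, 0.0) == (0.0, 1.0)
        assert share_comparison(0.3, 0.0)[1] == math.inf


class TestEdgeStatistics:
    def test_worked_example(self):
        # disease group: 4 source members, 3 of them target members, p_d^y = 0.5
        table = make_table(
            {
                "grp": ["d"] * 6 + ["c"] * 4,
                "src": ["yes"] * 4 + ["no"] * 2 + ["no"] * 4,
                "tgt": ["yes", "yes", "yes", "no", "no", "no", "yes", "no", "no", "no"],
            },
            {"grp": "binary", "src": "binary", "tgt": "binary"},
        )
        assignment = assign_cohorts(
            table, CohortSpec(criteria=[Criterion("grp", "equals", "d")])
        )
        _, inc = derive_attributes(table, {})
        tgt_stats = node_statistics(inc, assignment, inc.attribute("tgt=yes"))
        assert tgt_stats.p_d == 0.5
        e = edge_statistics(
            inc, assignment, inc.attribute("src=yes"), inc.attribute("tgt=yes"), tgt_stats
        )
        assert e.o_d == 3
        assert e.q_d == 0.75
        assert e.dprime_d == 0.25
        assert e.gprime_d == 1.5

    def test_identical_membership_perfect_implication(self):
        table = make_table(
            {
                "grp": ["d", "d", "c", "c"],
                "src": ["yes", "no", "yes", "no"],
                "tgt": ["yes", "no", "yes", "no"],
            },
            {"grp": "binary", "src": "binary", "tgt": "binary"},
        )
        assignment = assign_cohorts(
            table, CohortSpec(criteria=[Criterion("grp", "equals", "d")])
        )
        _, inc = derive_attributes(table, {})
        tgt_stats = node_statistics(inc, assignment, inc.attribute("tgt=yes"))
        e = edge_statistics(
            inc, assignment, inc.attribute("src=yes"), inc.attribute("tgt=yes"), tgt_stats
        )
        assert e.q_d == 1.0 and e.q_c == 1.0
        assert e.dprime_d == 1.0 - tgt_stats.p_d
        assert e.dprime_c == 1.0 - tgt_stats.p_c

    def test_disjoint_membership(self):
        table = make_table(
            {
                "grp": ["d", "d", "c", "c"],
                "src": ["yes", "no", "yes", "no"],
                "tgt": ["no", "yes", "no", "yes"],
            },
            {"grp": "binary", "src": "binary", "tgt": "binary"},
        )
        assignment = assign_cohorts(
            table, CohortSpec(criteria=[Criterion("grp", "equals", "d")])
        )
        _, inc = derive_attributes(table, {})
        tgt_stats = node_statistics(inc, assignment, inc.attribute("tgt=yes"))
        e = edge_statistics(
            inc, assignment, inc.attribute("src=yes"), inc.attribute("tgt=yes"), tgt_stats
        )
        assert e.o_d == 0 and e.q_d == 0.0
        assert e.dprime_d == -tgt_stats.p_d

    def test_source_and_target_must_differ(self):
        table = make_table({"grp": ["d", "c"], "src": ["yes", "no"]},
                           {"grp": "binary", "src": "binary"})
        assignment = assign_cohorts(
            table, CohortSpec(criteria=[Criterion("grp", "equals", "d")])
        )
        _, inc = derive_attributes(table, {})
        stats = node_statistics(inc, assignment, inc.attribute("src=yes"))
        with pytest.raises(ValueError):
            edge_statistics(
                inc, assignment, inc.attribute("src=yes"), inc.attribute("src=yes"), stats
            )


class TestEdgeType:
    def test_high_by_delta(self):
        assert (
            assign_edge_type(0.25, 0.05, 1.3, 1.2) == "high_cond_diff"
        )

    def test_medium_by_gamma(self):
        assert (
            assign_edge_type(0.05, 0.04, 1.6, 1.4) == "medium_cond_diff"
        )

    def test_low_below_everything(self):
        assert (
            assign_edge_type(0.02, 0.01, 1.1, 1.05) == "low_cond_diff"
        )

    def test_all_undefined_returns_none(self):
        assert assign_edge_type(None, None, None, None) is None

    def test_one_group_suffices(self):
        assert assign_edge_type(0.3, None, None, None) == "high_cond_diff"

    def test_suppressive_magnitude(self):
        # strong negative impact surfaces as high when typed by magnitude
        assert assign_edge_type(-0.25, None, 0.4, None) == "high_cond_diff"
        assert (
            assign_edge_type(-0.25, None, 0.4, None, magnitude=False) == "low_cond_diff"
        )

    def test_group_restricted_aggregation(self):
        assert assign_edge_type(0.25, 0.01, None, None, aggregation="control") == "low_cond_diff"
        assert assign_edge_type(0.25, 0.01, None, None, aggregation="disease") == "high_cond_diff"


class TestBuildGraph:
    def test_two_binary_variables(self):
        table = make_table(
            {
                "grp": ["d"] * 5 + ["c"] * 5,
                "a": ["yes", "no"] * 5,
                "b": ["yes", "yes", "no", "no", "yes"] * 2,
            },
            {"grp": "binary", "a": "binary", "b": "binary"},
        )
        spec = CohortSpec(criteria=[Criterion("grp", "equals", "d")])
        graph = build_graph(table, spec)
        # grp contributes 2 nodes as well; a & b give 4; cross-variable
        # ordered pairs among {grp,a,b} attributes: up to 6*4=24, a/b-only: 12
        ab_nodes = [aid for aid in graph.nodes if aid.split("=")[0] in ("a", "b")]
        ab_edges = [
            e
            for e in graph.edges
            if e.source_id.split("=")[0] in ("a", "b")
            and e.target_id.split("=")[0] in ("a", "b")
        ]
        assert len(ab_nodes) == 4
        assert len(ab_edges) <= 12

    def test_single_metric_variable_has_no_edges(self):
        table = make_table(
            {"grp": ["d", "d", "c", "c"], "v": [1.0, 2.0, 3.0, 4.0]},
            {"grp": "binary", "v": "metric"},
        )
        spec = CohortSpec(criteria=[Criterion("grp", "equals", "d")])
        graph = build_graph(table, spec, config=GraphConfig(same_variable_edges=False))
        v_nodes = [aid for aid in graph.nodes if aid.startswith("v=")]
        v_edges = [
            e for e in graph.edges
            if e.source_id.startswith("v=") and e.target_id.startswith("v=")
        ]
        assert len(v_nodes) == 3
        assert v_edges == []

    def test_empty_group_is_build_error(self):
        table = make_table({"grp": ["c", "c"]}, {"grp": "binary"})
        spec = CohortSpec(criteria=[Criterion("grp", "equals", "d")])
        with pytest.raises(BuildError, match="empty group"):
            build_graph(table, spec)

    def test_row_and_column_permutation_invariance(self):
        table, _, cohort_spec, _ = simulate_cohort(small_simulation_spec(seed=3, g_d=60, g_c=90))
        graph = build_graph(table, cohort_spec)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(table.data))
        cols = list(table.data.columns)
        rng.shuffle(cols)
        shuffled = make_like = table.data.iloc[perm][cols]
        table2 = type(table)(data=shuffled, meta=table.meta)
        graph2 = build_graph(table2, cohort_spec)
        assert set(graph.nodes) == set(graph2.nodes)
        for aid in graph.nodes:
            assert graph.nodes[aid] == graph2.nodes[aid]
        e1 = {(e.source_id, e.target_id): e for e in graph.edges}
        e2 = {(e.source_id, e.target_id): e for e in graph2.edges}
        assert e1 == e2

    def test_duality_under_group_swap(self):
        table, _, cohort_spec, _ = simulate_cohort(small_simulation_spec(seed=4, g_d=80, g_c=120))
        graph = build_graph(table, cohort_spec)
        swapped_spec = CohortSpec(
            criteria=[Criterion("cohort_flag", "equals", "control")],
            disease_name="control",
            control_name="disease",
        )
        swapped = build_graph(table, swapped_spec)
        mapping = {
            "highly_related": "highly_inverse",
            "related": "inverse",
            "unrelated": "unrelated",
            "inverse": "related",
            "highly_inverse": "highly_related",
        }
        for aid, stats in graph.nodes.items():
            other = swapped.nodes[aid]
            if stats.distinction_label is None:
                assert other.distinction_label is None
                continue
            assert other.distinction_label == mapping[stats.distinction_label]
            assert other.frequency_label == stats.frequency_label
        co1 = {(e.source_id, e.target_id): (e.o_d, e.o_c) for e in graph.edges}
        co2 = {(e.source_id, e.target_id): (e.o_c, e.o_d) for e in swapped.edges}
        assert co1 == co2

    def test_matches_brute_force_oracle(self):
        table, _, cohort_spec, _ = simulate_cohort(small_simulation_spec(seed=9, g_d=70, g_c=110))
        graph = build_graph(table, cohort_spec)
        assignment = assign_cohorts(table, cohort_spec)
        rows = table_to_rows(table)
        disease_ids = set(assignment.membership[assignment.disease_mask()].index)
        nodes, edges = oracle_graph(rows, table.meta, disease_ids)
        assert set(graph.nodes) == set(nodes)
        for aid, expected in nodes.items():
            got = graph.nodes[aid]
            for field, value in expected.items():
                assert getattr(got, field) == value, (aid, field)
        got_edges = {(e.source_id, e.target_id): e for e in graph.edges}
        assert set(got_edges) == set(edges)
        for key, expected in edges.items():
            got = got_edges[key]
            for field, value in expected.items():
                assert getattr(got, field) == value, (key, field)
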