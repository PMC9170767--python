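import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import funhop as fh


def make_cm(data, groups):
    df = pd.DataFrame(data).astype(float)  # outer keys = samples (columns)
    return fh.CountMatrix(
        counts=df, groups=pd.Series(groups, index=df.columns)
    )


class TestCountMatrix:
    def test_negative_counts_rejected(self):
        with pytest.raises(fh.ExpressionError, match="negative"):
            make_cm({"s1": {"A": -1.0, "B": 2.0},
                     "s2": {"A": 1.0, "B": 2.0}},
                    {"s1": "case", "s2": "control"})

    def test_unlabelled_sample_rejected(self):
        with pytest.raises(fh.ExpressionError, match="s2"):
            make_cm({"s1": {"A": 1.0}, "s2": {"A": 1.0}}, {"s1": "case"})

    def test_tsv_round_trip(self, small_cm, tmp_path):
        small_cm.to_tsv(tmp_path / "c.tsv", tmp_path / "g.tsv")
        back = fh.CountMatrix.from_tsv(tmp_path / "c.tsv", tmp_path / "g.tsv")
        pd.testing.assert_frame_equal(back.counts, small_cm.counts)
        assert list(back.groups) == list(small_cm.groups)


class TestLengthAdjust:
    def test_hand_arithmetic(self):
        # lengths 1000 and 3000, mean 2000 -> factors 0.5 and 1.5
        cm = make_cm(
            {"s1": {"A": 30.0, "B": 30.0}, "s2": {"A": 30.0, "B": 30.0}},
            {"s1": "case", "s2": "control"},
        )
        gl = fh.GeneLengths(length={"A": 1000.0, "B": 3000.0})
        adj = fh.length_adjust(cm, gl)
        assert adj.counts.loc["A", "s1"] == pytest.approx(60.0)
        assert adj.counts.loc["B", "s1"] == pytest.approx(20.0)

    def test_gene_at_mean_length_unchanged(self):
        cm = make_cm(
            {"s1": {"A": 10.0, "B": 10.0, "C": 10.0},
             "s2": {"A": 10.0, "B": 10.0, "C": 10.0}},
            {"s1": "case", "s2": "control"},
        )
        gl = fh.GeneLengths(length={"A": 1000.0, "B": 2000.0, "C": 3000.0})
        adj = fh.length_adjust(cm, gl)
        assert adj.counts.loc["B", "s1"] == pytest.approx(10.0)

    def test_mean_of_factors_is_one(self, small_cm):
        rng = np.random.default_rng(0)
        gl = fh.GeneLengths(length={
            g: float(rng.uniform(500, 10000)) for g in small_cm.genes
        })
        mean_len = np.mean(list(gl.length.values()))
        factors = [gl.length[g] / mean_len for g in small_cm.genes]
        assert np.mean(factors) == pytest.approx(1.0, abs=1e-12)

    def test_shared_length_preserves_totals(self, small_cm):
        gl = fh.GeneLengths(length={g: 1500.0 for g in small_cm.genes})
        adj = fh.length_adjust(small_cm, gl)
        assert adj.counts.to_numpy().sum() == pytest.approx(
            small_cm.counts.to_numpy().sum()
        )

    def test_missing_length_keeps_raw_counts_and_flags(self, small_cm):
        gl = fh.GeneLengths(length={
            g: 2000.0 for g in small_cm.genes if g != "HDC"
        })
        adj = fh.length_adjust(small_cm, gl)
        assert adj.flags["length_unadjusted"] == ["HDC"]
        pd.testing.assert_series_equal(
            adj.counts.loc["HDC"], small_cm.counts.loc["HDC"]
        )

    def test_empty_intersection_is_hard_error(self, small_cm):
        with pytest.raises(fh.ExpressionError, match="no overlap"):
            fh.length_adjust(small_cm, fh.GeneLengths(length={"ZZZ": 1.0}))


class TestMeanGroupExpression:
    def test_two_step_mean(self):
        cm = make_cm(
            {"c1": {"A": 100.0}, "c2": {"A": 100.0}, "n1": {"A": 50.0}},
            {"c1": "case", "c2": "case", "n1": "control"},
        )
        assert fh.mean_group_expression(cm)["A"] == pytest.approx(75.0)

    def test_balanced_groups_equal_plain_mean(self, small_cm):
        avg = fh.mean_group_expression(small_cm)
        pd.testing.assert_series_equal(
            avg, small_cm.counts.mean(axis=1), check_names=False
        )

    def test_unbalanced_matches_brute_force(self):
        rng = np.random.default_rng(5)
        data = {f"s{i}": {"A": float(rng.integers(0, 100)),
                          "B": float(rng.integers(0, 100))}
                for i in range(7)}
        groups = {f"s{i}": ("case" if i < 2 else "control") for i in range(7)}
        cm = make_cm(data, groups)
        avg = fh.mean_group_expression(cm)
        for gene in ("A", "B"):
            case_vals = [data[s][gene] for s in data if groups[s] == "case"]
            ctrl_vals = [data[s][gene] for s in data if groups[s] == "control"]
            expected = (np.mean(case_vals) + np.mean(ctrl_vals)) / 2
            assert avg[gene] == pytest.approx(expected)

    def test_empty_group_is_error(self):
        cm = make_cm({"s1": {"A": 1.0}, "s2": {"A": 1.0}},
                     {"s1": "case", "s2": "case"})
        with pytest.raises(fh.ExpressionError, match="control"):
            fh.mean_group_expression(cm)


class TestNodeMembership:
    def test_single_gene_node_suffix_one(self, histidine_pathway, aliases):
        nodes = fh.node_membership(histidine_pathway, aliases)
        by_id = {n.node_id: n for n in nodes}
        assert by_id["2"].agg_name == "HDC-B1"

    def test_multi_gene_naming(self, histidine_pathway, aliases):
        by_id = {n.node_id: n
                 for n in fh.node_membership(histidine_pathway, aliases)}
        assert by_id["1"].agg_name == "ALDH3A1-B4"
        assert by_id["1"].first_gene == "ALDH3A1"

    def test_pre_and_post_expansion_membership_identical(
        self, histidine_pathway, aliases
    ):
        pre = fh.node_membership(histidine_pathway, aliases)
        post = fh.node_membership(
            fh.expand_pathway(histidine_pathway, aliases), aliases
        )
        assert [(n.node_id, n.agg_name, n.members) for n in pre] == \
            [(n.node_id, n.agg_name, n.members) for n in post]

    def test_collision_gets_ordinal(self, aliases):
        pw = fh.Pathway(name="path:t")
        for eid in ("1", "2", "3"):
            pw.entries.append(fh.Entry(
                id=eid, type="gene", name="hsa:218 hsa:220",
                graphics=fh.Graphics(shape="rectangle", x=1.0, y=1.0,
                                     width=46.0, height=17.0),
            ))
        names = [n.agg_name for n in fh.node_membership(pw, aliases)]
        assert names == ["ALDH3A1-B2", "ALDH3A1-B2.2", "ALDH3A1-B2.3"]
        assert len(set(names)) == len(names)

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_agg_names_unique_on_simulated_pathways(self, seed):
        pw, aliases = fh.simulate_pathway(30, 10, seed)
        names = [n.agg_name for n in fh.node_membership(pw, aliases)]
        assert len(set(names)) == len(names)


class TestAggregateCounts:
    def test_sum_of_members(self):
        cm = make_cm({"s1": {"A": 10.0, "B": 5.0},
                      "s2": {"A": 1.0, "B": 2.0}},
                     {"s1": "case", "s2": "control"})
        node = fh.NodeModel(node_id="1", members=["A", "B"],
                            agg_name="A-B2")
        agg = fh.aggregate_counts(cm, [node])
        assert agg.counts.loc["A-B2", "s1"] == 15.0

    def test_absent_member_contributes_zero_with_flag(self):
        cm = make_cm({"s1": {"A": 10.0}, "s2": {"A": 1.0}},
                     {"s1": "case", "s2": "control"})
        node = fh.NodeModel(node_id="1", members=["ZZZ"], agg_name="ZZZ-B1")
        agg = fh.aggregate_counts(cm, [node])
        assert agg.counts.loc["ZZZ-B1"].tolist() == [0.0, 0.0]
        assert agg.flags["missing_members"] == {"ZZZ-B1": ["ZZZ"]}

    def test_matches_brute_force_double_loop(self):
        pw, aliases = fh.simulate_pathway(15, 8, seed=11)
        nodes = fh.node_membership(pw, aliases)
        truth = fh.plan_truth(nodes, seed=11)
        cm, _ = fh.simulate_counts(nodes, 3, 3, truth)
        agg = fh.aggregate_counts(cm, nodes)
        for node in nodes:
            for sample in cm.samples:
                expected = 0.0
                for gene in node.members:
                    if gene in cm.counts.index:
                        expected += cm.counts.loc[gene, sample]
                assert agg.counts.loc[node.agg_name, sample] == expected

    def test_linearity(self, small_cm):
        nodes = [fh.NodeModel(node_id="1",
                              members=["ALDH3A1", "ALDH1A3"],
                              agg_name="ALDH3A1-B2")]
        doubled = fh.CountMatrix(counts=small_cm.counts * 2,
                                 groups=small_cm.groups)
        a = fh.aggregate_counts(small_cm, nodes).counts
        b = fh.aggregate_counts(doubled, nodes).counts
        pd.testing.assert_frame_equal(a + a, b)


class TestNodeExpression:
    def test_dominant_phospholipase(self):
        # the 21-gene phospholipase node: PLA2G2A towers over the rest,
        # and the displayed gene PLA2G4B is absent from the dataset
        pw, aliases = fh.pla2_fixture()
        (node,) = fh.node_membership(pw, aliases)
        assert node.agg_name == "PLA2G4B-B21"
        avg = {m: 10.0 for m in node.members if m != "PLA2G4B"}
        avg["PLA2G2A"] = 71_482.0
        avg["PLA2G12A"] = 4_502.0
        expr = fh.node_expression(node, avg)
        assert expr.dominant == "PLA2G2A"
        assert expr.missing == ["PLA2G4B"]
        assert expr.ratios["PLA2G2A"] > 0.9

    def test_single_member_ratio_one(self):
        node = fh.NodeModel(node_id="1", members=["HDC"], agg_name="HDC-B1")
        expr = fh.node_expression(node, {"HDC": 42.0})
        assert expr.ratios == {"HDC": 1.0}
        assert expr.dominant == "HDC"

    def test_zero_total_degenerate(self):
        node = fh.NodeModel(node_id="1", members=["A", "B"], agg_name="A-B2")
        expr = fh.node_expression(node, {"A": 0.0, "B": 0.0})
        assert expr.total == 0.0
        assert expr.dominant is None
        assert all(r == 0.0 for r in expr.ratios.values())

    def test_tie_alphabetical_with_flag(self):
        node = fh.NodeModel(node_id="1", members=["B", "A"], agg_name="B-B2")
        expr = fh.node_expression(node, {"A": 5.0, "B": 5.0})
        assert expr.dominant == "A"
        assert expr.tie

    @settings(max_examples=30, deadline=None)
    @given(values=st.lists(
        st.floats(0, 1e6, allow_nan=False), min_size=1, max_size=25,
    ))
    def test_ratios_sum_to_one_when_total_positive(self, values):
        members = [f"g{i}" for i in range(len(values))]
        node = fh.NodeModel(node_id="1", members=members,
                            agg_name=f"g0-B{len(members)}")
        expr = fh.node_expression(node, dict(zip(members, values)))
        if expr.total > 0:
            assert sum(expr.ratios.values()) == pytest.approx(1.0, abs=1e-9)


class TestConcordance:
    def _exprs(self, noise_seed, nodes, truth_seed):
        truth = fh.plan_truth(nodes, seed=truth_seed, p_up=0, p_down=0)
        cm, _ = fh.simulate_counts(nodes, 20, 20, truth,
                                   noise_seed=noise_seed)
        avg = fh.mean_group_expression(cm)
        return [fh.node_expression(n, avg) for n in nodes], truth

    def test_identity_gives_perfect_concordance(self):
        pw, aliases = fh.simulate_pathway(10, 8, seed=2)
        nodes = fh.node_membership(pw, aliases)
        exprs, _ = self._exprs(2, nodes, truth_seed=2)
        res = fh.cohort_ratio_concordance(exprs, exprs)
        assert (res.pairs.ratio_a == res.pairs.ratio_b).all()
        assert all(rho == pytest.approx(1.0)
                   for rho in res.node_correlations.values())

    def test_pseudo_cohorts_share_dominant_genes(self):
        # two independent count draws over the same planted truth behave
        # like two cohorts: the high-ratio class is stable
        pw, aliases = fh.simulate_pathway(12, 10, seed=3)
        nodes = fh.node_membership(pw, aliases)
        exprs_a, truth = self._exprs(31, nodes, truth_seed=3)
        exprs_b, _ = self._exprs(32, nodes, truth_seed=3)
        res = fh.cohort_ratio_concordance(exprs_a, exprs_b)
        for ea, eb in zip(exprs_a, exprs_b):
            assert ea.dominant == eb.dominant
        assert res.high_class_stable

    def test_zero_total_node_excluded_with_flag(self):
        node = fh.NodeModel(node_id="1", members=["A", "B"], agg_name="A-B2")
        e_a = fh.node_expression(node, {"A": 1.0, "B": 3.0})
        e_b = fh.node_expression(node, {"A": 0.0, "B": 0.0})
        res = fh.cohort_ratio_concordance([e_a], [e_b])
        assert res.excluded_nodes == ["A-B2"]
        assert "A-B2" not in res.node_correlations

    def test_mismatched_node_sets_rejected(self):
        node1 = fh.NodeModel(node_id="1", members=["A"], agg_name="A-B1")
        node2 = fh.NodeModel(node_id="2", members=["B"], agg_name="B-B1")
        e1 = fh.node_expression(node1, {"A": 1.0})
        e2 = fh.node_expression(node2, {"B": 1.0})
        with pytest.raises(fh.ExpressionError, match="differ"):
            fh.cohort_ratio_concordance([e1], [e2])
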