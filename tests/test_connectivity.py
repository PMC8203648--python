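"""Differential FC: pooling, thresholding, per-edge tests, composite nets."""

import numpy as np
import pandas as pd
import pytest

from stimfc import build_costim_paradigm
from stimfc import synthetic as syn
from stimfc.connectivity import (
    CLIP,
    CompositeNetwork,
    DiffFCMatrix,
    FCMatrix,
    aggregate_composite,
    compare_conditions,
    diff_fc,
    fc_matrix,
    fisher_z,
    group_mean_fc,
    pseudo_direct,
    remove_global_mean,
    threshold_fc,
)
from stimfc.regional import RegionTimecourses

from test_regional import tc_from_frame


def fc_from_array(arr: np.ndarray, regions=None) -> FCMatrix:
    regions = regions or list(range(1, arr.shape[0] + 1))
    a = arr.astype(float).copy()
    np.fill_diagonal(a, np.nan)
    return FCMatrix(values=pd.DataFrame(a, index=regions, columns=regions))


def simulate_group_fc(spec, group, n_subjects, seed0, n_regions=10,
                      paradigm=None, global_mean=False):
    """Per-subject FC matrices from the region-level generator."""
    paradigm = paradigm or build_costim_paradigm()
    mats = []
    for i in range(n_subjects):
        df, _ = syn.simulate_region_timecourses(
            paradigm, n_regions, spec, group, seed=seed0 + i
        )
        tc = tc_from_frame(df, units="raw", subject=f"{group}{i}")
        if global_mean:
            tc = remove_global_mean(tc)
        mats.append(fc_matrix(tc))
    return mats


class TestRemoveGlobalMean:
    def test_cross_region_mean_zero(self, rng):
        df = pd.DataFrame(rng.standard_normal((6, 50)), index=range(1, 7))
        out = remove_global_mean(tc_from_frame(df))
        assert np.max(np.abs(out.data.mean(axis=0))) < 1e-12

    def test_identical_regions_become_zero(self, rng):
        row = rng.standard_normal(40)
        df = pd.DataFrame([row, row], index=[1, 2])
        out = remove_global_mean(tc_from_frame(df))
        assert np.allclose(out.data, 0.0)

    def test_shared_signal_invariance(self, rng):
        df = pd.DataFrame(rng.standard_normal((5, 60)), index=range(1, 6))
        shared = rng.standard_normal(60)
        out1 = remove_global_mean(tc_from_frame(df))
        out2 = remove_global_mean(tc_from_frame(df + shared))
        assert np.allclose(out1.data, out2.data, atol=1e-10)

    def test_single_region_rejected(self):
        df = pd.DataFrame(np.ones((1, 10)), index=[1])
        with pytest.raises(ValueError):
            remove_global_mean(tc_from_frame(df))


class TestFCMatrix:
    def test_copy_gives_unit_correlation(self, rng):
        row = rng.standard_normal(50)
        df = pd.DataFrame([row, row.copy()], index=[1, 2])
        fc = fc_matrix(tc_from_frame(df))
        assert fc.values.loc[1, 2] == pytest.approx(1.0)

    def test_negation_gives_minus_one(self, rng):
        row = rng.standard_normal(50)
        df = pd.DataFrame([row, -row], index=[1, 2])
        fc = fc_matrix(tc_from_frame(df))
        assert fc.values.loc[1, 2] == pytest.approx(-1.0)

    def test_three_region_textbook_oracle(self):
        """Hand-computed Pearson r for a 3-region toy."""
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        z = np.array([1.0, 1.0, 2.0, 0.0])

        def pearson(u, v):
            uc, vc = u - u.mean(), v - v.mean()
            return (uc @ vc) / np.sqrt((uc @ uc) * (vc @ vc))

        fc = fc_matrix(tc_from_frame(pd.DataFrame([x, y, z], index=[1, 2, 3])))
        assert fc.values.loc[1, 2] == pytest.approx(pearson(x, y), abs=1e-12)
        assert fc.values.loc[1, 3] == pytest.approx(pearson(x, z), abs=1e-12)
        assert fc.values.loc[2, 3] == pytest.approx(pearson(y, z), abs=1e-12)

    def test_constant_region_flagged_not_zero_filled(self, rng):
        df = pd.DataFrame(
            [rng.standard_normal(30), np.full(30, 2.0)], index=[1, 2]
        )
        fc = fc_matrix(tc_from_frame(df))
        assert fc.undefined_regions == (2,)
        assert np.isnan(fc.values.loc[1, 2])

    def test_too_short_rejected(self):
        df = pd.DataFrame(np.ones((2, 2)), index=[1, 2])
        with pytest.raises(ValueError):
            fc_matrix(tc_from_frame(df))

    def test_symmetry(self, rng):
        df = pd.DataFrame(rng.standard_normal((5, 40)), index=range(1, 6))
        v = fc_matrix(tc_from_frame(df)).values.to_numpy()
        assert np.allclose(v, v.T, equal_nan=True)


class TestFisherPooling:
    def test_round_trip_identity(self):
        r = np.linspace(-0.999, 0.999, 101)
        back = np.tanh(fisher_z(r))
        assert np.max(np.abs(back - r)) < 1e-9

    def test_single_matrix_unchanged(self, rng):
        df = pd.DataFrame(rng.standard_normal((4, 50)), index=range(1, 5))
        fc = fc_matrix(tc_from_frame(df))
        pooled = group_mean_fc([fc])
        assert np.allclose(
            pooled.values.to_numpy(), fc.values.to_numpy(),
            atol=1e-12, equal_nan=True,
        )

    def test_zero_mean(self):
        a = fc_from_array(np.zeros((2, 2)))
        assert group_mean_fc([a, a]).values.loc[1, 2] == 0.0

    def test_direct_evaluation_oracle(self):
        a = fc_from_array(np.array([[1.0, 0.5], [0.5, 1.0]]))
        b = fc_from_array(np.array([[1.0, 0.8], [0.8, 1.0]]))
        pooled = group_mean_fc([a, b])
        expected = np.tanh((np.arctanh(0.5) + np.arctanh(0.8)) / 2)
        assert pooled.values.loc[1, 2] == pytest.approx(expected, abs=1e-12)

    def test_undefined_entries_averaged_over_defined_subset(self):
        a = fc_from_array(np.array([[1.0, np.nan], [np.nan, 1.0]]))
        b = fc_from_array(np.array([[1.0, 0.6], [0.6, 1.0]]))
        pooled = group_mean_fc([a, b])
        assert pooled.values.loc[1, 2] == pytest.approx(0.6)

    def test_symmetry_preserved(self, rng):
        mats = []
        for _ in range(3):
            df = pd.DataFrame(rng.standard_normal((5, 60)), index=range(1, 6))
            mats.append(fc_matrix(tc_from_frame(df)))
        v = group_mean_fc(mats).values.to_numpy()
        assert np.allclose(v, v.T, equal_nan=True)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            group_mean_fc([])

    def test_region_order_mismatch_rejected(self, rng):
        a = fc_from_array(np.eye(2), regions=[1, 2])
        b = fc_from_array(np.eye(2), regions=[2, 3])
        with pytest.raises(ValueError):
            group_mean_fc([a, b])


class TestThresholdFC:
    def test_mean_degree_k10_at_protocol_scale(self, rng):
        """100 selected regions, 500 edges per channel -> k = 10."""
        n = 100
        m = rng.uniform(-1, 1, (n, n))
        m = (m + m.T) / 2
        fc = fc_from_array(m)
        th = threshold_fc(fc, n_pos=500, n_neg=500)
        assert th.degree("positive") == pytest.approx(10.0)
        assert th.degree("negative") == pytest.approx(10.0)
        assert len(th.positive) == 500 and len(th.negative) == 500

    def test_all_negative_leaves_positive_channel_empty(self):
        m = -np.abs(np.random.default_rng(0).uniform(0.1, 1, (5, 5)))
        m = (m + m.T) / 2
        th = threshold_fc(fc_from_array(m), n_pos=3, n_neg=3)
        assert len(th.positive) == 0
        assert len(th.negative) == 3

    def test_matches_full_sort_oracle(self, rng):
        """Edge sets agree with a brute-force sort of all pairs."""
        n = 30
        m = rng.uniform(-1, 1, (n, n))
        m = (m + m.T) / 2
        fc = fc_from_array(m)
        th = threshold_fc(fc, n_pos=40, n_neg=40)
        pairs = [
            (i + 1, j + 1, m[i, j])
            for i in range(n)
            for j in range(i + 1, n)
        ]
        pos_oracle = {
            (a, b)
            for a, b, r in sorted(
                [p for p in pairs if p[2] > 0], key=lambda p: -p[2]
            )[:40]
        }
        neg_oracle = {
            (a, b)
            for a, b, r in sorted(
                [p for p in pairs if p[2] < 0], key=lambda p: p[2]
            )[:40]
        }
        assert th.edge_set("positive") == pos_oracle
        assert th.edge_set("negative") == neg_oracle

    def test_invariant_to_monotone_transform_within_sign(self, rng):
        n = 20
        m = rng.uniform(-1, 1, (n, n))
        m = (m + m.T) / 2
        th1 = threshold_fc(fc_from_array(m), n_pos=15, n_neg=15)
        # strictly monotone odd transform preserving sign classes
        th2 = threshold_fc(fc_from_array(np.tanh(3 * m)), n_pos=15, n_neg=15)
        assert th1.edge_set("positive") == th2.edge_set("positive")
        assert th1.edge_set("negative") == th2.edge_set("negative")

    def test_fewer_available_keeps_all_with_warning(self):
        m = np.array([[0, 0.5, -0.2], [0.5, 0, 0.1], [-0.2, 0.1, 0]])
        with pytest.warns(UserWarning, match="keeping all"):
            th = threshold_fc(fc_from_array(m), n_pos=10, n_neg=10)
        assert len(th.positive) == 2
        assert len(th.negative) == 1

    def test_restriction_to_selected_regions(self, rng):
        n = 10
        m = rng.uniform(-1, 1, (n, n))
        m = (m + m.T) / 2
        th = threshold_fc(fc_from_array(m), regions=[1, 2, 3], n_pos=2, n_neg=2)
        for a, b in th.edge_set("positive") | th.edge_set("negative"):
            assert a in (1, 2, 3) and b in (1, 2, 3)

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError):
            threshold_fc(fc_from_array(np.eye(3)), regions=[99])


NULL_SPEC = syn.EffectSpec(noise_sd=0.2)
PLANT_SPEC = syn.EffectSpec(
    couplings=(
        syn.CouplingSpec(1, 2, "positive", {"treated": 0.8}),
    ),
    noise_sd=0.2,
)


class TestDiffFC:
    def test_identical_groups_all_zero(self, rng):
        mats = simulate_group_fc(NULL_SPEC, "g", 4, seed0=0)
        d = diff_fc(mats[:2] + mats[2:], mats[:2] + mats[2:])
        for mat in d.indicators.values():
            assert (mat.to_numpy() == 0).all()

    def test_planted_coupling_detected_with_sign(self):
        """Coupling 0.8 present only in the treated group: the edge is
        flagged +1 (treated > control) in >= 90 % of seeds at n = 5 vs 9."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            ctrl = simulate_group_fc(PLANT_SPEC, "control", 5, seed0=1000 * seed)
            trt = simulate_group_fc(PLANT_SPEC, "treated", 9, seed0=1000 * seed + 500)
            d = diff_fc(ctrl, trt)
            if d.indicators["positive"].loc[1, 2] == 1:
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_null_rejection_rate_matches_alpha(self):
        """Null cohorts over the full edge universe: the mean fraction of
        nonzero indicators approximates alpha (+/- 0.02 over 100 seeds)."""
        fracs = []
        paradigm = build_costim_paradigm(n_heat=4, n_volumes=250)
        for seed in range(100):
            ctrl = simulate_group_fc(
                NULL_SPEC, "c", 5, seed0=10_000 + 37 * seed, paradigm=paradigm
            )
            trt = simulate_group_fc(
                NULL_SPEC, "t", 9, seed0=20_000 + 37 * seed, paradigm=paradigm
            )
            d = diff_fc(ctrl, trt, alpha=0.05)
            fracs.append(d.nonzero_fraction())
        assert abs(np.mean(fracs) - 0.05) <= 0.02

    def test_group_label_swap_negates_indicators(self):
        """Exchangeability symmetry: relabeling the groups flips every
        signed indicator (homoscedastic t test is symmetric)."""
        ctrl = simulate_group_fc(NULL_SPEC, "c", 3, seed0=7)
        trt = simulate_group_fc(NULL_SPEC, "t", 4, seed0=77)
        d1 = diff_fc(ctrl, trt)
        d2 = diff_fc(trt, ctrl)
        for ch in d1.indicators:
            assert np.array_equal(
                d1.indicators[ch].to_numpy(), -d2.indicators[ch].to_numpy()
            )

    def test_universe_restricts_testing(self):
        ctrl = simulate_group_fc(PLANT_SPEC, "control", 3, seed0=3)
        trt = simulate_group_fc(PLANT_SPEC, "treated", 3, seed0=33)
        gm_c, gm_t = group_mean_fc(ctrl), group_mean_fc(trt)
        th_c = threshold_fc(gm_c, n_pos=1, n_neg=0)
        th_t = threshold_fc(gm_t, n_pos=1, n_neg=0)
        d = diff_fc(ctrl, trt, edge_universe=(th_c, th_t))
        universe = th_c.edge_set("positive") | th_t.edge_set("positive")
        nz = np.argwhere(d.indicators["positive"].to_numpy() != 0)
        for i, j in nz:
            pair = tuple(sorted((d.regions[i], d.regions[j])))
            assert pair in universe
        assert (d.indicators["negative"].to_numpy() == 0).all()

    def test_paired_requires_equal_sizes(self):
        mats = simulate_group_fc(NULL_SPEC, "g", 5, seed0=0)
        with pytest.raises(ValueError, match="paired"):
            diff_fc(mats[:2], mats[2:], test="paired")

    def test_small_groups_rejected(self):
        mats = simulate_group_fc(NULL_SPEC, "g", 3, seed0=0)
        with pytest.raises(ValueError):
            diff_fc(mats[:1], mats[1:])


def diff_from_indicators(regions, channel_entries, alpha=0.05):
    """Build a DiffFCMatrix from explicit {(a, b): sign} per channel."""
    indicators = {}
    for ch in ("positive", "negative"):
        mat = pd.DataFrame(
            np.zeros((len(regions), len(regions)), dtype=int),
            index=regions, columns=regions,
        )
        for (a, b), s in channel_entries.get(ch, {}).items():
            mat.loc[a, b] = s
            mat.loc[b, a] = s
        indicators[ch] = mat
    return DiffFCMatrix(indicators=indicators, alpha=alpha, test="homoscedastic")


class TestAggregateComposite:
    def test_seven_control_one_treated_gives_minus_six(self):
        """Seven control-greater and one treated-greater constituent
        connections aggregate to a net FC of -6."""
        regions = list(range(1, 10))  # 1..8 in U, 9 in V
        entries = {
            "positive": {(r, 9): -1 for r in range(1, 8)},
            "negative": {(8, 9): +1},
        }
        d = diff_from_indicators(regions, entries)
        membership = {r: "U" for r in range(1, 9)} | {9: "V"}
        net = aggregate_composite(d, membership)
        assert net.net.loc["U", "V"] == -6
        assert net.net.loc["V", "U"] == -6

    def test_all_zero_diff_gives_empty_network(self):
        d = diff_from_indicators([1, 2, 3], {})
        net = aggregate_composite(d, {1: "A", 2: "B", 3: "B"})
        assert net.edges() == []

    def test_display_threshold_monotone(self):
        regions = list(range(1, 11))
        entries = {
            "positive": {(r, 10): -1 for r in range(1, 8)},
            "negative": {(1, 9): -1, (2, 9): -1, (3, 9): -1, (4, 9): -1, (5, 9): -1},
        }
        d = diff_from_indicators(regions, entries)
        membership = {r: "A" for r in range(1, 9)} | {9: "B", 10: "C"}
        at4 = aggregate_composite(d, membership, display_threshold=4)
        at6 = aggregate_composite(d, membership, display_threshold=6)
        assert at6.edge_set() <= at4.edge_set()

    def test_within_composite_indicators_not_edges(self):
        d = diff_from_indicators([1, 2], {"positive": {(1, 2): 1}})
        net = aggregate_composite(d, {1: "A", 2: "A"})
        assert net.edges() == []
        assert net.net.loc["A", "A"] == 1  # retained on the diagonal

    def test_uncovered_region_rejected(self):
        d = diff_from_indicators([1, 2], {})
        with pytest.raises(ValueError, match="cover"):
            aggregate_composite(d, {1: "A"})


class TestPseudoDirect:
    @staticmethod
    def _net(edges, nodes):
        net = pd.DataFrame(
            np.zeros((len(nodes), len(nodes)), dtype=int),
            index=nodes, columns=nodes,
        )
        for (u, v), w in edges.items():
            net.loc[u, v] = w
            net.loc[v, u] = w
        return CompositeNetwork(net=net, display_threshold=0)

    def test_single_prior_entry_directs_edge(self):
        net = self._net({("A", "B"): -5}, ["A", "B"])
        prior = pd.DataFrame(
            [[0, 1], [0, 0]], index=["A", "B"], columns=["A", "B"]
        )
        out = pseudo_direct(net, prior)
        assert out.directions[("A", "B")] == "ab"

    def test_empty_prior_leaves_undirected(self):
        net = self._net({("A", "B"): 3}, ["A", "B"])
        prior = pd.DataFrame(
            np.zeros((2, 2)), index=["A", "B"], columns=["A", "B"]
        )
        out = pseudo_direct(net, prior)
        assert out.directions[("A", "B")] is None

    def test_random_prior_matches_lookup_oracle(self, rng):
        nodes = [f"N{i}" for i in range(6)]
        edges = {}
        for i in range(6):
            for j in range(i + 1, 6):
                edges[(nodes[i], nodes[j])] = int(rng.integers(-5, 6)) or 1
        net = self._net(edges, nodes)
        prior = pd.DataFrame(
            rng.integers(0, 2, (6, 6)), index=nodes, columns=nodes
        )
        out = pseudo_direct(net, prior)
        for e in out.edges():
            u, v = e["source"], e["target"]
            fwd, rev = bool(prior.loc[u, v]), bool(prior.loc[v, u])
            expected = (
                "both" if fwd and rev else "ab" if fwd else "ba" if rev else None
            )
            assert out.directions[(u, v)] == expected


class TestCompareConditions:
    def test_identical_networks_full_overlap(self):
        net = TestPseudoDirect._net({("A", "B"): 5, ("A", "C"): -7}, ["A", "B", "C"])
        res = compare_conditions(net, net)
        assert res["overlap"] == 2 == res["n_a"] == res["n_b"]

    def test_disjoint_networks_zero_overlap(self):
        n1 = TestPseudoDirect._net({("A", "B"): 5}, ["A", "B", "C"])
        n2 = TestPseudoDirect._net({("A", "C"): 5}, ["A", "B", "C"])
        assert compare_conditions(n1, n2)["overlap"] == 0

    def test_toy_three_of_five_shared(self):
        nodes = list("ABCDEF")
        e1 = {("A", "B"): 1, ("A", "C"): 1, ("A", "D"): 1, ("B", "C"): 1, ("B", "D"): 1}
        e2 = {("A", "B"): 1, ("A", "C"): 1, ("B", "C"): 1, ("C", "D"): 1,
              ("C", "E"): 1, ("D", "E"): 1}
        res = compare_conditions(
            TestPseudoDirect._net(e1, nodes), TestPseudoDirect._net(e2, nodes)
        )
        assert res["overlap"] == 3

    def test_strength_comparison(self):
        nodes = ["A", "B"]
        net = TestPseudoDirect._net({("A", "B"): 2}, nodes)
        sa = pd.DataFrame([[0, 0.9], [0.9, 0]], index=nodes, columns=nodes)
        sb = pd.DataFrame([[0, 0.4], [0.4, 0]], index=nodes, columns=nodes)
        res = compare_conditions(net, net, sa, sb)
        assert res["strength_a_vs_b"][("A", "B")] == "stronger"

    def test_node_space_mismatch_rejected(self):
        n1 = TestPseudoDirect._net({("A", "B"): 1}, ["A", "B"])
        n2 = TestPseudoDirect._net({("A", "C"): 1}, ["A", "C"])
        with pytest.raises(ValueError):
            compare_conditions(n1, n2)


SHARED_PLUS_PLANTED = syn.EffectSpec(
    couplings=(
        # background coupling present in both groups
        syn.CouplingSpec(50, 60, "positive", {"control": 0.6, "treated": 0.6}),
        # group-specific planted coupling, stronger than the background
        syn.CouplingSpec(1, 2, "positive", {"treated": 0.8}),
    ),
    noise_sd=0.2,
)
E2E_MEMBERSHIP = (
    {1: "A", 2: "B", 50: "C", 60: "D"}
    | {r: "rest" for r in range(1, 101) if r not in (1, 2, 50, 60)}
)


def run_fc_chain(seed: int, spec=SHARED_PLUS_PLANTED, n_regions=100,
                 n_pos=1, n_neg=0, membership=E2E_MEMBERSHIP):
    """Region simulation -> global-mean removal -> FC -> Fisher pooling ->
    thresholding -> differential tests -> composite aggregation."""
    ctrl = simulate_group_fc(
        spec, "control", 5, seed0=seed * 1000, n_regions=n_regions,
        global_mean=True,
    )
    trt = simulate_group_fc(
        spec, "treated", 9, seed0=seed * 1000 + 500, n_regions=n_regions,
        global_mean=True,
    )
    th = tuple(
        threshold_fc(group_mean_fc(g), n_pos=n_pos, n_neg=n_neg)
        for g in (ctrl, trt)
    )
    d = diff_fc(ctrl, trt, edge_universe=th)
    return aggregate_composite(d, membership, display_threshold=0)


class TestEndToEndRecovery:
    def test_planted_composite_edge_recovered(self):
        """With one group-specific coupling planted on top of a shared
        background edge, the displayed composite network contains exactly
        the planted edge in >= 90 % of 50 seeds."""
        exact = 0
        for seed in range(50):
            net = run_fc_chain(seed)
            if net.edge_set() == {("A", "B")}:
                assert net.net.loc["A", "B"] == 1  # treated > control
                exact += 1
        assert exact >= 45

    def test_null_cohort_net_fc_bounded(self):
        """Identical group effects: expected |net FC| per composite edge
        stays below 2 x alpha x constituent count."""
        n_regions, alpha = 12, 0.05
        membership = {r: ("A" if r <= 6 else "B") for r in range(1, n_regions + 1)}
        n_constituents = 6 * 6 * 2  # cross pairs x two channels
        nets = []
        for seed in range(20):
            ctrl = simulate_group_fc(
                NULL_SPEC, "c", 5, seed0=31_000 + 101 * seed, n_regions=n_regions
            )
            trt = simulate_group_fc(
                NULL_SPEC, "t", 9, seed0=62_000 + 101 * seed, n_regions=n_regions
            )
            d = diff_fc(ctrl, trt, alpha=alpha)
            net = aggregate_composite(d, membership)
            nets.append(abs(int(net.net.loc["A", "B"])))
        assert np.mean(nets) <= 2 * alpha * n_constituents

    def test_fc_recovery_planted_pair_ranks_top(self):
        """The planted coupled pair ranks within the thresholded top edges
        of the treated group's mean FC in >= 95 % of seeds."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            trt = simulate_group_fc(
                PLANT_SPEC, "treated", 9, seed0=90_000 + 13 * seed
            )
            th = threshold_fc(group_mean_fc(trt), n_pos=3, n_neg=3)
            if (1, 2) in th.edge_set("positive"):
                hits += 1
        assert hits >= 0.95 * n_seeds
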