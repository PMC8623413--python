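"""Parsimony mapping of acquisitions and the Poisson gain:loss estimator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ytraffic import io, reference
from ytraffic.gainloss import (
    EventMap,
    Scenario,
    build_event_map,
    estimate_ratio,
    infer_acquisition_branch,
    infer_all,
)
from ytraffic.simdata import simulate_event_history


class TestInferAcquisitionBranch:
    def test_recent_gain_beats_ancestral_y(self, caterpillar_tree):
        # Y in the focal species, autosomal in five progressively more
        # distant outgroups: one recent duplication plus one source-copy
        # loss (cost 2) beats any ancestral-Y scenario
        states = {"focal": "Y", "o1": "XA", "o2": "XA", "o3": "XA", "o4": "XA", "o5": "XA"}
        sc = infer_acquisition_branch(states, caterpillar_tree)
        assert sc.gain_edge == "focal"
        assert sc.cost == 2
        assert sc.source_loss_edges == ("focal",)
        assert sc.y_loss_edges == ()

    def test_all_y_leaves_root_acquisition(self, caterpillar_tree):
        leaves = ["focal", "o1", "o2", "o3", "o4", "o5"]
        sc = infer_acquisition_branch({lf: "Y" for lf in leaves}, caterpillar_tree)
        assert sc.gain_edge == "root"

    def test_all_unknown_rejected(self, balanced_tree):
        with pytest.raises(ValueError):
            infer_acquisition_branch({}, balanced_tree)

    def test_missing_leaves_treated_as_unknown(self, balanced_tree):
        sc = infer_acquisition_branch({"A": "Y"}, balanced_tree)
        assert sc.cost >= 1

    def test_matches_exhaustive_enumeration_on_balanced_tree(self, balanced_tree):
        from itertools import product

        leaves = ["A", "B", "C", "D"]
        for combo in product(["Y", "XA", "absent", "unknown"], repeat=4):
            if "Y" not in combo:
                continue
            states = dict(zip(leaves, combo))
            sc = infer_acquisition_branch(states, balanced_tree)
            best_cost, best_edges = reference.parsimony_enumerate(states, balanced_tree)
            assert sc.cost == best_cost, states
            assert {sc.gain_edge} | set(sc.tied_gain_edges) == best_edges, states

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        states=st.lists(
            st.sampled_from(["Y", "XA", "absent", "unknown"]), min_size=6, max_size=6
        )
    )
    def test_matches_enumeration_on_caterpillar(self, states):
        tree = io.tree_from_newick(
            "(((((focal:1,o1:1):1,o2:2):1,o3:3):1,o4:4):1,o5:5);"
        )
        leaves = ["focal", "o1", "o2", "o3", "o4", "o5"]
        if "Y" not in states:
            return
        mapping = dict(zip(leaves, states))
        sc = infer_acquisition_branch(mapping, tree)
        best_cost, best_edges = reference.parsimony_enumerate(mapping, tree)
        assert sc.cost == best_cost
        assert {sc.gain_edge} | set(sc.tied_gain_edges) == best_edges


class TestBuildEventMap:
    def test_basal_gains_aggregate_on_root(self, caterpillar_tree):
        scenarios = {
            f"g{i}": Scenario(f"g{i}", "root", (), (), 1) for i in range(8)
        }
        emap = build_event_map(scenarios, caterpillar_tree)
        assert len(emap.gains["root"]) == 8
        assert all(not v for v in emap.losses.values())

    def test_empty_scenarios_empty_map(self, caterpillar_tree):
        emap = build_event_map({}, caterpillar_tree)
        G, L, _, Tl = emap.totals()
        assert (G, L, Tl) == (0, 0, 0.0)

    def test_loss_before_gain_rejected(self, caterpillar_tree):
        bad = {"g": Scenario("g", "focal", ("o5",), (), 2)}
        with pytest.raises(ValueError):
            build_event_map(bad, caterpillar_tree)

    def test_gain_count_equals_genes_with_y_state(self, caterpillar_tree):
        leaves = ["focal", "o1", "o2", "o3", "o4", "o5"]
        presence = {
            "g1": {lf: "Y" for lf in leaves},
            "g2": {"focal": "Y", "o1": "XA", "o2": "XA", "o3": "XA", "o4": "XA", "o5": "XA"},
            "g3": {"focal": "Y", "o1": "Y", "o2": "XA", "o3": "XA", "o4": "XA", "o5": "XA"},
        }
        scenarios = infer_all(presence, caterpillar_tree)
        emap = build_event_map(scenarios, caterpillar_tree)
        assert emap.totals()[0] == 3  # one gain per gene: single-origin

    def test_simulated_history_round_trips(self):
        tree = io.tree_from_newick("((((A:5,B:5):5,C:10):5,D:15):5,E:20);")
        emap, truth = simulate_event_history(tree, 0.4, 0.05, seed=61)
        assert emap.totals()[0] == truth["n_gains"]
        assert emap.totals()[1] == truth["n_losses"]
        # gain exposure is the branch time, identical across genes
        total_time = sum(e.length or 0 for e in tree.preorder_edge_iter())
        assert emap.totals()[2] == pytest.approx(total_time)


def _simple_map(G, L, Tg, Tl):
    return EventMap(
        tree=None,
        gains={"b": [f"g{i}" for i in range(G)]},
        losses={"b": [f"g{i}" for i in range(L)]},
        gain_exposure={"b": Tg},
        loss_exposure={"b": Tl},
    )


class TestEstimateRatio:
    def test_symmetric_null_gives_ratio_one_p_one(self):
        est = estimate_ratio(_simple_map(10, 10, 50.0, 50.0))
        assert est.ratio_hat == pytest.approx(1.0)
        assert est.p_value == pytest.approx(1.0)
        assert est.ci_low < 1.0 < est.ci_high

    def test_no_losses_is_flagged_lower_bound(self):
        est = estimate_ratio(_simple_map(12, 0, 50.0, 50.0))
        assert est.flagged
        assert math.isinf(est.ratio_hat)
        assert math.isinf(est.ci_high)
        assert est.ci_low > 0 and math.isfinite(est.ci_low)

    def test_no_gains_is_flagged_upper_bound(self):
        est = estimate_ratio(_simple_map(0, 8, 50.0, 50.0))
        assert est.flagged
        assert est.ratio_hat == 0.0
        assert math.isfinite(est.ci_high)

    def test_exposure_normalization(self):
        # same counts, loss exposure doubled: ratio doubles
        a = estimate_ratio(_simple_map(20, 4, 100.0, 100.0))
        b = estimate_ratio(_simple_map(20, 4, 100.0, 200.0))
        assert b.ratio_hat == pytest.approx(2 * a.ratio_hat)

    def test_determinism(self):
        m = _simple_map(17, 3, 80.0, 140.0)
        e1, e2 = estimate_ratio(m), estimate_ratio(m)
        assert (e1.ratio_hat, e1.ci_low, e1.ci_high) == (e2.ratio_hat, e2.ci_low, e2.ci_high)

    def test_ci_contains_point_estimate(self):
        est = estimate_ratio(_simple_map(30, 5, 70.0, 500.0))
        assert est.ci_low <= est.ratio_hat <= est.ci_high

    def test_log_ratio_bias_shrinks_with_event_count(self):
        # estimator consistency: more events, smaller bias of log(ratio)
        tree = io.tree_from_newick("((((A:5,B:5):5,C:10):5,D:15):5,E:20);")
        bias = []
        for gain_rate in (0.3, 3.0):
            logs = []
            for i in range(150):
                emap, _ = simulate_event_history(tree, gain_rate, gain_rate / 10, seed=7000 + i)
                G, L, _, _ = emap.totals()
                if G == 0 or L == 0:
                    continue
                logs.append(math.log(estimate_ratio(emap).ratio_hat))
            bias.append(abs(np.mean(logs) - math.log(10.0)))
        assert bias[1] < bias[0] + 0.05
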