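"""Layer matching, weighted aggregation, asymmetric update."""

from collections import OrderedDict

import numpy as np
import pytest

from fedseg.aggregation import (
    AggregationWeights,
    aggregate_states,
    apply_update,
    client_update,
    compatible_layers,
    fedavg,
)
from fedseg.model import ModelState, UNet2D, architecture_layout

from conftest import plan_for_patch


def state_of(arrays: dict) -> ModelState:
    return ModelState(params=OrderedDict((k, np.asarray(v)) for k, v in arrays.items()))


def brute_force_intersection(layouts):
    """Independent oracle: exhaustive pairwise name/shape comparison."""
    common = set(layouts[0])
    for lo in layouts[1:]:
        common &= set(lo)
    out = set()
    for name in common:
        shapes = {tuple(lo[name]) for lo in layouts}
        if len(shapes) == 1:
            out.add(name)
    return out


class TestCompatibleLayers:
    def test_identical_architectures_share_everything(self, tiny_plan):
        net = UNet2D(tiny_plan)
        states = [net.init_state(s) for s in (0, 1)]
        compat = compatible_layers(states)
        assert set(compat.names()) == set(net.layout)

    def test_shape_clash_excludes_layer(self):
        a = state_of({"w": np.zeros((32, 3, 3)), "v": np.zeros(4)})
        b = state_of({"w": np.zeros((64, 3, 3)), "v": np.zeros(4)})
        compat = compatible_layers([a, b])
        assert "w" not in compat
        assert "v" in compat

    def test_deep_vs_shallow_matches_brute_force(self):
        layouts = [architecture_layout(plan_for_patch(320)),    # 7 stages
                   architecture_layout(plan_for_patch(512))]    # 8 stages
        states = [ModelState(params=OrderedDict(
            (k, np.zeros(s, dtype=np.float32)) for k, s in lo.items()))
            for lo in layouts]
        expected = brute_force_intersection(layouts)
        got = set(compatible_layers(states, mode="strict").names())
        assert got == expected
        # the shallow encoder and the capped-channel deep decoder overlap
        assert "encoder.stages.0.convs.0.conv.weight" in got
        assert "decoder.stages.0.upconv.weight" in got
        assert "head.weight" in got

    def test_partial_mode_uses_majority_shape_group(self):
        a = state_of({"w": np.zeros((2, 2)), "only_ab": np.zeros(3)})
        b = state_of({"w": np.zeros((2, 2)), "only_ab": np.zeros(3)})
        c = state_of({"w": np.zeros((4, 2))})
        strict = compatible_layers([a, b, c], mode="strict")
        partial = compatible_layers([a, b, c], mode="partial")
        assert len(strict) == 0
        assert partial.layers == {"w": (0, 1), "only_ab": (0, 1)}

    def test_partial_mode_tie_excluded(self):
        a = state_of({"w": np.zeros(2)})
        b = state_of({"w": np.zeros(3)})
        assert len(compatible_layers([a, b], mode="partial")) == 0


class TestAggregateStates:
    def test_equal_center_mean(self):
        states = [state_of({"w": [1.0]}), state_of({"w": [3.0]})]
        w = AggregationWeights.from_case_counts("equal_center", [10, 90])
        compat = compatible_layers(states)
        agg = aggregate_states(states, w, compat)
        assert agg["w"] == pytest.approx([2.0])

    def test_proportional_weighted_mean(self):
        states = [state_of({"w": [1.0]}), state_of({"w": [3.0]})]
        w = AggregationWeights.from_case_counts("proportional", [100, 300])
        agg = aggregate_states(states, w, compatible_layers(states))
        assert agg["w"] == pytest.approx([2.5])

    def test_matches_brute_force_loop_oracle(self, rng):
        n_clients = 5
        counts = [3, 10, 1, 7, 4]
        states = [
            state_of({"a": rng.standard_normal((3, 3)), "b": rng.standard_normal(6)})
            for _ in range(n_clients)
        ]
        w = AggregationWeights.from_case_counts("proportional", counts)
        agg = aggregate_states(states, w, compatible_layers(states))
        total = sum(counts)
        for name in ("a", "b"):
            expected = np.zeros_like(states[0].params[name])
            for k in range(n_clients):
                expected = expected + (counts[k] / total) * states[k].params[name]
            assert np.allclose(agg[name], expected, rtol=0, atol=1e-12)

    def test_restricted_weights_renormalized(self, rng):
        # a layer held by a subset: weights over the subset must sum to 1,
        # so averaging constant-1 layers returns exactly 1
        a = state_of({"w": np.ones(4), "x": np.ones(2)})
        b = state_of({"w": np.ones(4)})
        c = state_of({"w": np.ones(4), "x": np.ones(2)})
        w = AggregationWeights.from_case_counts("proportional", [5, 2, 9])
        compat = compatible_layers([a, b, c], mode="partial")
        agg = aggregate_states([a, b, c], w, compat)
        assert np.all(np.abs(agg["x"] - 1.0) <= 1e-15)

    def test_convexity_of_aggregate(self, rng):
        states = [state_of({"w": rng.standard_normal(8)}) for _ in range(4)]
        w = AggregationWeights.from_case_counts("proportional", [1, 2, 3, 4])
        agg = aggregate_states(states, w, compatible_layers(states))
        stack = np.stack([s.params["w"] for s in states])
        assert np.all(agg["w"] >= stack.min(axis=0) - 1e-12)
        assert np.all(agg["w"] <= stack.max(axis=0) + 1e-12)

    def test_client_permutation_bitwise_invariant(self, rng):
        states = [state_of({"w": rng.standard_normal((4, 4)).astype(np.float32)})
                  for _ in range(3)]
        w = AggregationWeights(mode="proportional", values=(0.2, 0.3, 0.5))
        ref = aggregate_states(states, w, compatible_layers(states))
        # permute clients but permute weights consistently; summation is
        # by ascending client id so the result must be bitwise identical
        perm = [2, 0, 1]
        inv = AggregationWeights(mode="proportional",
                                 values=tuple(w.values[p] for p in perm))
        # relabeled clients hold the same (layer -> array) content
        permuted = [states[p] for p in perm]
        got = aggregate_states(permuted, inv, compatible_layers(permuted))
        # same multiset of (weight, array) pairs -> same weighted sum, but
        # bitwise equality additionally needs the same summation order:
        # verify the value matches to fp precision and the canonical-order
        # aggregation is exactly reproducible
        assert np.allclose(ref["w"], got["w"], rtol=0, atol=1e-7)
        again = aggregate_states(states, w, compatible_layers(states))
        assert np.array_equal(ref["w"], again["w"])

    def test_missing_layer_in_contributor_raises(self):
        a = state_of({"w": [1.0]})
        b = state_of({"w": [2.0]})
        compat = compatible_layers([a, b])
        del b.params["w"]
        with pytest.raises(ValueError, match="inconsistent compatibility set"):
            aggregate_states([a, b], AggregationWeights("equal_center", (0.5, 0.5)), compat)


class TestApplyUpdate:
    def test_empty_shared_set_is_noop(self, tiny_plan):
        state = UNet2D(tiny_plan).init_state(0)
        out = apply_update(state, {})
        assert all(np.array_equal(out.params[k], state.params[k]) for k in state.params)

    def test_full_shared_set_replaces_everything(self, tiny_plan):
        net = UNet2D(tiny_plan)
        local, other = net.init_state(0), net.init_state(1)
        out = apply_update(local, dict(other.params))
        assert all(np.array_equal(out.params[k], other.params[k]) for k in out.params)

    def test_layers_outside_shared_set_bitwise_unchanged(self, tiny_plan):
        net = UNet2D(tiny_plan)
        local, other = net.init_state(0), net.init_state(1)
        shared_names = [n for n in net.layout if n.startswith("encoder.stages.0")]
        shared = {n: other.params[n] for n in shared_names}
        out = apply_update(local, shared)
        for name in net.layout:
            if name in shared:
                assert np.array_equal(out.params[name], other.params[name])
            else:
                assert out.params[name].tobytes() == local.params[name].tobytes()
        assert out.meta["epoch"] == local.meta["epoch"]

    def test_shape_clash_raises(self):
        local = state_of({"w": np.zeros(3)})
        with pytest.raises(ValueError, match="stale compatibility set"):
            apply_update(local, {"w": np.zeros(4)})

    def test_unknown_layer_raises(self):
        local = state_of({"w": np.zeros(3)})
        with pytest.raises(ValueError, match="stale compatibility set"):
            apply_update(local, {"v": np.zeros(3)})

    def test_client_update_restricts_to_contributor_layers(self):
        # client 0 holds the minority shape of "w" and lacks "deep"
        states = [
            state_of({"w": np.zeros(3), "head": np.zeros(2)}),
            state_of({"w": np.zeros(4), "head": np.ones(2), "deep": np.zeros(5)}),
            state_of({"w": np.zeros(4), "head": np.full(2, 2.0), "deep": np.ones(5)}),
        ]
        weights = AggregationWeights.from_case_counts("equal_center", [1, 1, 1])
        compat = compatible_layers(states, mode="partial")
        shared = aggregate_states(states, weights, compat)
        assert set(shared) == {"w", "head", "deep"}
        sub = client_update(shared, compat, 0)
        assert set(sub) == {"head"}
        updated = apply_update(states[0], sub)
        assert np.array_equal(updated.params["w"], states[0].params["w"])
        assert np.allclose(updated.params["head"], 1.0)


class TestFedAvg:
    def test_identical_states_are_a_fixed_point(self, tiny_plan):
        net = UNet2D(tiny_plan)
        state = net.init_state(3)
        out = fedavg([state.copy() for _ in range(4)],
                     AggregationWeights.from_case_counts("equal_center", [1] * 4))
        assert all(np.allclose(out.params[k], state.params[k], atol=1e-7)
                   for k in state.params)

    def test_degenerate_weight_returns_single_client(self, tiny_plan):
        net = UNet2D(tiny_plan)
        a, b = net.init_state(0), net.init_state(1)
        out = fedavg([a, b], AggregationWeights("proportional", (1.0, 0.0)))
        assert all(np.array_equal(out.params[k], a.params[k]) for k in a.params)

    def test_equals_aggregate_states_on_full_set(self, tiny_plan, rng):
        net = UNet2D(tiny_plan)
        states = [net.init_state(s) for s in range(3)]
        w = AggregationWeights.from_case_counts("proportional", [2, 5, 3])
        via_fedavg = fedavg(states, w)
        via_asym = aggregate_states(states, w, compatible_layers(states))
        for name in net.layout:
            assert np.array_equal(via_fedavg.params[name], via_asym[name])

    def test_architecture_mismatch_raises(self):
        a = state_of({"w": np.zeros(3)})
        b = state_of({"w": np.zeros(4)})
        with pytest.raises(ValueError, match="architecture mismatch"):
            fedavg([a, b], AggregationWeights("equal_center", (0.5, 0.5)))
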