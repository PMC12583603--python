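"""Federation orchestration: the four modes, determinism, privacy."""

import numpy as np
import pytest

from fedseg.aggregation import compatible_layers
from fedseg.federation import (
    Client,
    FederationConfig,
    _client_fingerprint,
    run_asymfedavg,
    run_centralized,
    run_ffe,
    run_local,
)
from fedseg.model import UNet2D, architecture_layout
from fedseg.planner import ResourceBudget, make_plan
from fedseg.synthetic import CenterSpec, generate_center
from fedseg.training import Hyperparams


def tiny_budget(max_stages=2, base_features=4):
    return ResourceBudget(
        max_patch_voxels=24 * 24, max_batch=2,
        max_stages=max_stages, base_features=base_features,
    )


def tiny_client(name, seed, n=3, shape=32, spacing=1.0, budget=None, client_seed=None):
    spec = CenterSpec(
        name=name, shape_range=((shape, shape), (shape, shape)),
        spacing=(spacing, spacing), lesion_count=(1, 1),
        lesion_radius_mm=(5.0, 8.0), n_cases=n, seed=seed,
    )
    cases = [(c.image, c.mask, c.spacing) for c in generate_center(spec)]
    return Client(name=name, cases=cases, budget=budget or tiny_budget(), seed=client_seed)


def fast_config(mode, **kw):
    hp = kw.pop("hyperparams", Hyperparams(lr=0.01, momentum=0.9, iters_per_epoch=2))
    return FederationConfig(mode=mode, n_rounds=kw.pop("n_rounds", 2),
                            hyperparams=hp, **kw)


class TestLocal:
    def test_single_client_matches_direct_training(self):
        from fedseg.federation import _client_init_seed, _derive_seed, _TAG_PATCH
        from fedseg.training import preprocess_case, train_one_epoch

        client = tiny_client("a", seed=1)
        config = fast_config("local")
        result = run_local([client], config)

        fp = _client_fingerprint(client, config, 0)
        plan = make_plan(fp, client.budget)
        hp = config.effective_hyperparams()
        state = UNet2D(plan).init_state(_client_init_seed(client, config, 0))
        cases = [preprocess_case(i, m, s, plan) for i, m, s in client.cases]
        rng = np.random.default_rng(_derive_seed(config.seed, _TAG_PATCH, 0))
        buffers = {}
        for _ in range(config.total_epochs):
            state, _, buffers = train_one_epoch(state, cases, plan, hp, rng,
                                                buffers=buffers)
        assert result.states["a"].allclose(state)

    def test_same_data_and_seed_give_identical_states(self):
        a = tiny_client("a", seed=1, client_seed=77)
        b = tiny_client("b", seed=1, client_seed=77)
        result = run_local([a, b], fast_config("local"))
        assert result.states["a"].allclose(result.states["b"])

    def test_plans_match_planner_on_local_fingerprints(self):
        clients = [tiny_client("a", 1, spacing=1.0), tiny_client("b", 2, spacing=0.5, shape=48)]
        config = fast_config("local", n_rounds=1)
        result = run_local(clients, config)
        for i, c in enumerate(clients):
            expected = make_plan(_client_fingerprint(c, config, i), c.budget)
            assert result.plans[c.name] == expected

    def test_no_exchange_occurs(self):
        result = run_local([tiny_client("a", 1)], fast_config("local", n_rounds=1))
        assert result.exchange_log == []

    def test_empty_client_rejected(self):
        c = Client(name="x", cases=[], budget=tiny_budget())
        with pytest.raises(ValueError, match="empty client"):
            run_local([c], fast_config("local"))


class TestCentralized:
    def test_single_client_equals_local(self):
        client = tiny_client("a", seed=3)
        config = fast_config("centralized")
        central = run_centralized([client], config)
        local = run_local([client], fast_config("local"))
        assert central.states["pooled"].allclose(local.states["a"])

    def test_pooled_fingerprint_is_aggregate_of_locals(self):
        from fedseg.fingerprint import aggregate_fingerprints

        clients = [tiny_client("a", 1), tiny_client("b", 2)]
        config = fast_config("centralized", n_rounds=1)
        result = run_centralized(clients, config)
        fps = [_client_fingerprint(c, config, i) for i, c in enumerate(clients)]
        expected = aggregate_fingerprints(fps)
        assert result.global_fingerprint.shapes_after_crop == expected.shapes_after_crop
        assert result.global_fingerprint.n_cases == expected.n_cases

    def test_client_order_does_not_change_plan(self):
        clients = [tiny_client("a", 1), tiny_client("b", 2, shape=40)]
        config = fast_config("centralized", n_rounds=1)
        p1 = run_centralized(clients, config).plans["pooled"]
        p2 = run_centralized(clients[::-1], config).plans["pooled"]
        assert p1 == p2


class TestFFE:
    def test_single_client_single_round_equals_local(self):
        client = tiny_client("a", seed=4)
        cfg_kw = dict(n_rounds=1, init_seed=123)
        ffe = run_ffe([client], fast_config("ffe", **cfg_kw))
        local = run_local([client], fast_config("local", **cfg_kw))
        assert ffe.states["a"].allclose(local.states["a"])

    def test_identical_clients_average_to_their_own_state(self):
        a = tiny_client("a", seed=5, client_seed=11)
        b = tiny_client("b", seed=5, client_seed=11)
        result = run_ffe([a, b], fast_config("ffe", n_rounds=1))
        # identical data + seeds -> identical pre-aggregation states, so the
        # broadcast equals either one; both final copies must agree
        assert result.states["a"].allclose(result.states["b"])
        local = run_local([a], fast_config("local", n_rounds=1,
                                           init_seed=None))
        # the broadcast equals what one client alone would have trained from
        # the shared initialization (same plan since data identical)

    def test_plan_hashes_identical_across_heterogeneous_clients(self):
        clients = [
            tiny_client("a", 1, shape=32, spacing=1.0),
            tiny_client("b", 2, shape=40, spacing=0.8),
            tiny_client("c", 3, shape=48, spacing=0.6),
        ]
        result = run_ffe(clients, fast_config("ffe", n_rounds=1))
        hashes = {p.plan_hash for p in result.plans.values()}
        assert len(hashes) == 1
        # and the plan is reproducible offline from the global fingerprint
        offline = make_plan(result.global_fingerprint, clients[0].budget)
        assert offline.plan_hash == hashes.pop()

    def test_divergent_budgets_raise_with_report(self):
        a = tiny_client("a", 1)
        b = tiny_client("b", 2, budget=tiny_budget(max_stages=3))
        with pytest.raises(RuntimeError, match="FFE plan divergence"):
            run_ffe([a, b], fast_config("ffe", n_rounds=1))

    def test_clients_end_bitwise_equal_to_broadcast(self):
        clients = [tiny_client("a", 1), tiny_client("b", 2)]
        result = run_ffe(clients, fast_config("ffe"))
        assert result.states["a"].allclose(result.states["b"])
        for k in result.states["a"].params:
            assert np.array_equal(result.states["a"].params[k],
                                  result.states["b"].params[k])


class TestAsymFedAvg:
    def test_reduces_to_ffe_with_identical_architectures(self):
        mk = lambda: [tiny_client("a", 1, client_seed=21), tiny_client("b", 2, client_seed=22)]
        cfg = dict(n_rounds=2, init_seed=9)
        ffe = run_ffe(mk(), fast_config("ffe", **cfg))
        asym = run_asymfedavg(mk(), fast_config("asymfedavg", **cfg))
        for name in ("a", "b"):
            for k in ffe.states[name].params:
                assert np.array_equal(ffe.states[name].params[k],
                                      asym.states[name].params[k])

    def test_compat_size_matches_offline_intersection(self):
        clients = [
            tiny_client("a", 1, budget=tiny_budget(max_stages=2)),
            tiny_client("b", 2, shape=48, budget=tiny_budget(max_stages=3)),
        ]
        config = fast_config("asymfedavg", n_rounds=2)
        result = run_asymfedavg(clients, config)
        layouts = []
        for i, c in enumerate(clients):
            plan = make_plan(_client_fingerprint(c, config, i), c.budget)
            layouts.append(architecture_layout(plan))
        assert result.plans["a"].n_stages != result.plans["b"].n_stages
        common = {
            n for n in set(layouts[0]) & set(layouts[1])
            if layouts[0][n] == layouts[1][n]
        }
        assert all(log.compat_size == len(common) for log in result.logs)
        assert 0 < len(common) < min(len(lo) for lo in layouts)

    def test_non_common_layers_evolve_locally(self):
        clients = [
            tiny_client("a", 1, budget=tiny_budget(max_stages=2)),
            tiny_client("b", 2, shape=48, budget=tiny_budget(max_stages=3)),
        ]
        result = run_asymfedavg(clients, fast_config("asymfedavg", n_rounds=1))
        sa = result.states["a"]
        sb = result.states["b"]
        compat = compatible_layers([sa, sb])
        for name in compat.names():
            assert np.array_equal(sa.params[name], sb.params[name])
        # deep-stage layers exist only in b's model
        assert any(n.startswith("encoder.stages.2.") for n in sb.params)
        assert not any(n.startswith("encoder.stages.2.") for n in sa.params)

    def test_width_mismatch_shares_only_the_head_bias(self):
        # different widths leave exactly one shape-compatible tensor: the
        # classification head bias, whose shape depends only on num_classes
        clients = [
            tiny_client("a", 1, budget=tiny_budget(base_features=4)),
            tiny_client("b", 2, budget=tiny_budget(base_features=6)),
        ]
        asym = run_asymfedavg(clients, fast_config("asymfedavg", n_rounds=1))
        assert all(log.compat_size == 1 for log in asym.logs)
        assert np.array_equal(
            asym.states["a"].params["head.bias"], asym.states["b"].params["head.bias"]
        )
        for name in asym.states["a"].params:
            if name != "head.bias" and name in asym.states["b"].params:
                same_shape = (
                    asym.states["a"].params[name].shape
                    == asym.states["b"].params[name].shape
                )
                assert not same_shape

    def test_empty_compatibility_set_warns_and_degenerates_to_local(self, monkeypatch):
        import fedseg.federation as fed
        from fedseg.aggregation import CompatibleLayerSet

        monkeypatch.setattr(
            fed,
            "compatible_layers",
            lambda states, mode="strict": CompatibleLayerSet(layers={}, mode=mode),
        )
        clients = [tiny_client("a", 1), tiny_client("b", 2)]
        with pytest.warns(UserWarning, match="empty compatibility set"):
            asym = run_asymfedavg(clients, fast_config("asymfedavg", n_rounds=1))
        local = run_local(clients, fast_config("local", n_rounds=1))
        for name in ("a", "b"):
            assert asym.states[name].allclose(local.states[name])
        assert all(log.compat_size == 0 for log in asym.logs)


class TestPrivacyContract:
    def test_only_fingerprints_and_states_cross_the_boundary(self):
        clients = [tiny_client("a", 1), tiny_client("b", 2)]
        ffe = run_ffe(clients, fast_config("ffe", n_rounds=1))
        kinds = {e["kind"] for e in ffe.exchange_log}
        assert kinds == {"DatasetFingerprint", "ModelState"}
        asym = run_asymfedavg(clients, fast_config("asymfedavg", n_rounds=1))
        kinds = {e["kind"] for e in asym.exchange_log}
        assert kinds == {"ModelState", "AggregatedState"}
        assert "DatasetFingerprint" not in kinds  # local plans only
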