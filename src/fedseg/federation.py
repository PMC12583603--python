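"""In-process federation orchestration for the four training modes.

``local``       — every client trains alone on its own fingerprint/plan.
``centralized`` — all data pooled into one dataset, one plan, one model.
``ffe``         — fingerprints are exchanged once, concatenated into a
                  global fingerprint, every client plans from it (plans
                  must come out identical), and classical FedAvg runs.
``asymfedavg``  — clients keep the architectures planned from their
                  *local* fingerprints; each round only name/shape
                  compatible layers are averaged and redistributed.

Clients and server communicate through explicit message passing recorded
in an exchange log: only fingerprints and model states ever cross the
client boundary, never images — the privacy contract a networked backend
would have to honor as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from fedseg.aggregation import (
    AggregationWeights,
    aggregate_states,
    apply_update,
    client_update,
    compatible_layers,
    fedavg,
)
from fedseg.fingerprint import DatasetFingerprint, aggregate_fingerprints, fingerprint_from_cases
from fedseg.model import ModelState, UNet2D
from fedseg.planner import ResourceBudget, TrainingPlan, make_plan
from fedseg.training import Hyperparams, preprocess_case, train_one_epoch

_TAG_INIT, _TAG_PATCH, _TAG_FP = 0, 1, 2


def _derive_seed(*keys: int) -> int:
    return int(np.random.SeedSequence(tuple(keys)).generate_state(1)[0] % 2**31)


@dataclass
class Client:
    """One simulated institution: private cases plus a resource budget."""

    name: str
    cases: list[tuple[np.ndarray, np.ndarray, tuple[float, ...]]]
    budget: ResourceBudget
    #: explicit client seed (patch sampling and, in local/asymfedavg
    #: modes, parameter init); when None both are derived from the run seed
    seed: int | None = None

    @classmethod
    def from_directory(cls, path, budget: ResourceBudget, name: str | None = None) -> "Client":
        from pathlib import Path

        from fedseg import nifti

        path = Path(path)
        ids = nifti.list_cases(path)
        cases = [nifti.read_case(path, cid) for cid in ids]
        return cls(name=name or path.name, cases=cases, budget=budget)

    @property
    def n_cases(self) -> int:
        return len(self.cases)


@dataclass
class FederationConfig:
    mode: Literal["local", "centralized", "ffe", "asymfedavg"]
    n_rounds: int = 30
    epochs_per_round: int = 1
    weighting: Literal["proportional", "equal_center"] = "proportional"
    seed: int = 0
    hyperparams: Hyperparams = field(default_factory=Hyperparams)
    partial_matching: bool = False
    #: override for parameter initialization (shared by all clients);
    #: lets e.g. an asymfedavg run start from the states an ffe run would
    init_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_rounds < 1 or self.epochs_per_round < 1:
            raise ValueError("n_rounds and epochs_per_round must be positive")

    @property
    def total_epochs(self) -> int:
        return self.n_rounds * self.epochs_per_round

    def effective_hyperparams(self) -> Hyperparams:
        # LR schedule runs over the global epoch count, identical on all
        # clients, so federated clients stay in lockstep.
        return replace(self.hyperparams, total_epochs=self.total_epochs)


@dataclass
class RoundLog:
    round: int
    losses: dict[str, float]
    compat_size: int
    weights: tuple[float, ...]
    broadcast_checksum: str | None


@dataclass
class FederationResult:
    states: "dict[str, ModelState]"
    plans: "dict[str, TrainingPlan]"
    logs: list[RoundLog]
    exchange_log: list[dict]
    global_fingerprint: DatasetFingerprint | None = None


def _check_clients(clients: Sequence[Client]) -> None:
    if not clients:
        raise ValueError("no clients")
    for c in clients:
        if c.n_cases == 0:
            raise ValueError(f"empty client: {c.name}")


def _client_fingerprint(client: Client, config: FederationConfig, idx: int) -> DatasetFingerprint:
    return fingerprint_from_cases(client.cases, seed=_derive_seed(config.seed, _TAG_FP, idx))


def _client_rngs(clients: Sequence[Client], config: FederationConfig) -> list[np.random.Generator]:
    return [
        np.random.default_rng(
            c.seed if c.seed is not None else _derive_seed(config.seed, _TAG_PATCH, i)
        )
        for i, c in enumerate(clients)
    ]


def _client_init_seed(client: Client, config: FederationConfig, idx: int) -> int:
    if config.init_seed is not None:
        return config.init_seed
    if client.seed is not None:
        return client.seed
    return _derive_seed(config.seed, _TAG_INIT, idx)


def _preprocess(client: Client, plan: TrainingPlan) -> list[tuple[np.ndarray, np.ndarray]]:
    return [preprocess_case(img, msk, sp, plan) for img, msk, sp in client.cases]


def _state_checksum(state: ModelState) -> str:
    from fedseg.io import _state_checksum as cks

    return cks(state.params)


def run_local(clients: Sequence[Client], config: FederationConfig) -> FederationResult:
    """Independent per-client training; no inter-client exchange."""
    _check_clients(clients)
    hp = config.effective_hyperparams()
    rngs = _client_rngs(clients, config)
    states: dict[str, ModelState] = {}
    plans: dict[str, TrainingPlan] = {}
    logs: list[RoundLog] = []
    per_client = []
    for i, client in enumerate(clients):
        fp = _client_fingerprint(client, config, i)
        plan = make_plan(fp, client.budget)
        plans[client.name] = plan
        net = UNet2D(plan, num_classes=hp.num_classes)
        state = net.init_state(_client_init_seed(client, config, i))
        per_client.append((client, state, _preprocess(client, plan), {}))
    for t in range(config.n_rounds):
        losses = {}
        for i, (client, state, cases, buffers) in enumerate(per_client):
            for _ in range(config.epochs_per_round):
                state, trace, buffers = train_one_epoch(
                    state, cases, plans[client.name], hp, rngs[i], buffers=buffers
                )
            per_client[i] = (client, state, cases, buffers)
            losses[client.name] = float(np.mean(trace))
        logs.append(RoundLog(t, losses, 0, (), None))
    for client, state, _, _ in per_client:
        states[client.name] = state
    return FederationResult(states=states, plans=plans, logs=logs, exchange_log=[])


def run_centralized(clients: Sequence[Client], config: FederationConfig) -> FederationResult:
    """Pool all data into one dataset and train a single model.

    The pooled fingerprint equals the aggregation of the locals by
    construction; the first client's budget is used (the centralized
    baseline assumes one training site).
    """
    _check_clients(clients)
    hp = config.effective_hyperparams()
    fps = [_client_fingerprint(c, config, i) for i, c in enumerate(clients)]
    fp = aggregate_fingerprints(fps)
    plan = make_plan(fp, clients[0].budget)
    pooled = Client(
        name="pooled",
        cases=[case for c in clients for case in c.cases],
        budget=clients[0].budget,
    )
    net = UNet2D(plan, num_classes=hp.num_classes)
    state = net.init_state(_client_init_seed(clients[0], config, 0))
    cases = _preprocess(pooled, plan)
    rng = np.random.default_rng(_derive_seed(config.seed, _TAG_PATCH, 0))
    buffers: dict = {}
    logs = []
    for t in range(config.n_rounds):
        for _ in range(config.epochs_per_round):
            state, trace, buffers = train_one_epoch(state, cases, plan, hp, rng, buffers=buffers)
        logs.append(RoundLog(t, {"pooled": float(np.mean(trace))}, 0, (), None))
    return FederationResult(
        states={"pooled": state},
        plans={"pooled": plan},
        logs=logs,
        exchange_log=[],
        global_fingerprint=fp,
    )


def _plan_divergence_report(plans: "dict[str, TrainingPlan]") -> str:
    dicts = {name: p.to_dict() for name, p in plans.items()}
    ref_name = next(iter(dicts))
    ref = dicts[ref_name]
    lines = []
    for name, d in dicts.items():
        for key in ref:
            if d[key] != ref[key]:
                lines.append(f"{name}.{key}={d[key]!r} != {ref_name}.{key}={ref[key]!r}")
    return "; ".join(lines)


def run_ffe(clients: Sequence[Client], config: FederationConfig) -> FederationResult:
    """Federated fingerprint extraction followed by classical FedAvg.

    Fingerprints cross the boundary exactly once, before training; the
    identical global fingerprint (with shared budgets) yields identical
    plans, verified by plan hash.
    """
    _check_clients(clients)
    hp = config.effective_hyperparams()
    exchange: list[dict] = []
    fps = []
    for i, client in enumerate(clients):
        fp = _client_fingerprint(client, config, i)
        exchange.append({"direction": "client_to_server", "client": client.name,
                         "kind": type(fp).__name__})
        fps.append(fp)
    global_fp = aggregate_fingerprints(fps)
    for client in clients:
        exchange.append({"direction": "server_to_client", "client": client.name,
                         "kind": type(global_fp).__name__})

    plans = {c.name: make_plan(global_fp, c.budget) for c in clients}
    hashes = {name: p.plan_hash for name, p in plans.items()}
    if len(set(hashes.values())) != 1:
        raise RuntimeError("FFE plan divergence: " + _plan_divergence_report(plans))
    plan = next(iter(plans.values()))

    net = UNet2D(plan, num_classes=hp.num_classes)
    shared_seed = config.init_seed if config.init_seed is not None else _derive_seed(
        config.seed, _TAG_INIT
    )
    broadcast = net.init_state(shared_seed)
    weights = AggregationWeights.from_case_counts(
        config.weighting, [c.n_cases for c in clients]
    )
    rngs = _client_rngs(clients, config)
    datasets = [_preprocess(c, plan) for c in clients]
    buffers: list[dict] = [{} for _ in clients]
    logs = []
    n_layers = len(net.layout)
    for t in range(config.n_rounds):
        locals_: list[ModelState] = []
        losses = {}
        for i, client in enumerate(clients):
            state = broadcast.copy()
            state.meta["epoch"] = t * config.epochs_per_round
            for _ in range(config.epochs_per_round):
                state, trace, buffers[i] = train_one_epoch(
                    state, datasets[i], plan, hp, rngs[i], buffers=buffers[i]
                )
            losses[client.name] = float(np.mean(trace))
            exchange.append({"direction": "client_to_server", "client": client.name,
                             "kind": type(state).__name__})
            locals_.append(state)
        broadcast = fedavg(locals_, weights)
        for client in clients:
            exchange.append({"direction": "server_to_client", "client": client.name,
                             "kind": type(broadcast).__name__})
        logs.append(
            RoundLog(t, losses, n_layers, weights.values, _state_checksum(broadcast))
        )
    states = {c.name: broadcast.copy() for c in clients}
    return FederationResult(
        states=states, plans=plans, logs=logs, exchange_log=exchange,
        global_fingerprint=global_fp,
    )


def run_asymfedavg(clients: Sequence[Client], config: FederationConfig) -> FederationResult:
    """Asymmetric aggregation over architectures planned from *local*
    fingerprints: no fingerprint exchange; each round only name/shape
    compatible layers are averaged, everything else evolves locally."""
    _check_clients(clients)
    hp = config.effective_hyperparams()
    exchange: list[dict] = []
    plans: dict[str, TrainingPlan] = {}
    states: list[ModelState] = []
    datasets = []
    for i, client in enumerate(clients):
        fp = _client_fingerprint(client, config, i)  # stays local
        plan = make_plan(fp, client.budget)
        plans[client.name] = plan
        net = UNet2D(plan, num_classes=hp.num_classes)
        states.append(net.init_state(_client_init_seed(client, config, i)))
        datasets.append(_preprocess(client, plan))
    weights = AggregationWeights.from_case_counts(
        config.weighting, [c.n_cases for c in clients]
    )
    rngs = _client_rngs(clients, config)
    buffers: list[dict] = [{} for _ in clients]
    logs = []
    match_mode = "partial" if config.partial_matching else "strict"
    for t in range(config.n_rounds):
        losses = {}
        for i, client in enumerate(clients):
            for _ in range(config.epochs_per_round):
                states[i], trace, buffers[i] = train_one_epoch(
                    states[i], datasets[i], plans[client.name], hp, rngs[i],
                    buffers=buffers[i],
                )
            losses[client.name] = float(np.mean(trace))
            exchange.append({"direction": "client_to_server", "client": client.name,
                             "kind": type(states[i]).__name__})
        compat = compatible_layers(states, mode=match_mode)
        checksum = None
        if len(compat) == 0:
            warnings.warn(
                "empty compatibility set: aggregation degenerates to local training",
                stacklevel=2,
            )
        else:
            shared = aggregate_states(states, weights, compat)
            for i, client in enumerate(clients):
                states[i] = apply_update(states[i], client_update(shared, compat, i))
                exchange.append({"direction": "server_to_client", "client": client.name,
                                 "kind": "AggregatedState"})
            import hashlib as _hashlib

            h = _hashlib.sha256()
            for name in sorted(shared):
                h.update(name.encode())
                h.update(np.ascontiguousarray(shared[name]).tobytes())
            checksum = h.hexdigest()
        logs.append(RoundLog(t, losses, len(compat), weights.values, checksum))
    return FederationResult(
        states={c.name: states[i] for i, c in enumerate(clients)},
        plans=plans, logs=logs, exchange_log=exchange,
    )


RUNNERS = {
    "local": run_local,
    "centralized": run_centralized,
    "ffe": run_ffe,
    "asymfedavg": run_asymfedavg,
}


def run_federation(clients: Sequence[Client], config: FederationConfig) -> FederationResult:
    return RUNNERS[config.mode](clients, config)
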