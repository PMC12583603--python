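"""Desk-scale federated benchmark harness.

Runs the training modes on a synthetic multi-center preset with small
networks (depth capped at 3 stages, 12 base features, 64x64 patches) so a
full comparison — local vs FFE vs AsymFedAvg over tens of rounds —
completes in minutes on one CPU core. Held-out evaluation uses mean
foreground Dice per center; the cross-center matrix is computed from the
local-mode models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from fedseg.federation import Client, FederationConfig, run_federation
from fedseg.metrics import cross_center_matrix, dsc
from fedseg.planner import ResourceBudget
from fedseg.synthetic import SyntheticCase, make_benchmark
from fedseg.training import Hyperparams, predict


def benchmark_budget() -> ResourceBudget:
    """Resource budget of the desk-scale benchmark clients."""
    return ResourceBudget(
        max_patch_voxels=64 * 64, max_batch=4, dimensionality=2,
        max_stages=3, base_features=12,
    )


def benchmark_hyperparams() -> Hyperparams:
    """Hyperparameters for short (tens of epochs) CPU runs: the upstream
    schedule shape with a faster base learning rate and lighter momentum,
    sized to the 30-epoch budget."""
    return Hyperparams(lr=0.03, momentum=0.95, nesterov=True, weight_decay=3e-5)


@dataclass
class BenchmarkResult:
    center_names: list[str]
    #: mode -> center -> mean foreground DSC on that center's held-out cases
    dsc_by_mode: dict
    #: local-mode cross-center DSC matrix (rows: training center)
    matrix: np.ndarray
    logs: dict = field(default_factory=dict)


def _split(cases: list[SyntheticCase], val_fraction: float) -> tuple[list, list]:
    n_val = max(1, int(round(len(cases) * val_fraction)))
    train = cases[: len(cases) - n_val]
    val = cases[len(cases) - n_val :]
    return train, val


def run_benchmark(
    seed: int,
    *,
    preset: str = "heterogeneous3",
    n_cases: int = 25,
    n_rounds: int = 30,
    modes: tuple[str, ...] = ("local", "ffe", "asymfedavg"),
    weighting: str = "proportional",
    val_fraction: float = 0.2,
    budget: ResourceBudget | None = None,
    hyperparams: Hyperparams | None = None,
) -> BenchmarkResult:
    """One full benchmark run (data generation, training, evaluation)."""
    budget = budget or benchmark_budget()
    hp = hyperparams or benchmark_hyperparams()
    data = make_benchmark(preset, seed=seed, n_cases=n_cases)
    names = list(data)
    train_val = {name: _split(cases, val_fraction) for name, cases in data.items()}
    clients = [
        Client(
            name=name,
            cases=[(c.image, c.mask, c.spacing) for c in train_val[name][0]],
            budget=budget,
        )
        for name in names
    ]
    val_sets = {
        name: [(c.image, c.mask, c.spacing) for c in train_val[name][1]] for name in names
    }

    dsc_by_mode: dict = {}
    logs: dict = {}
    local_models = None
    for mode in modes:
        config = FederationConfig(
            mode=mode, n_rounds=n_rounds, epochs_per_round=1,
            weighting=weighting, seed=seed, hyperparams=hp,
        )
        result = run_federation(clients, config)
        per_center = {}
        for name in names:
            if mode == "centralized":
                state, plan = result.states["pooled"], result.plans["pooled"]
            else:
                state, plan = result.states[name], result.plans[name]
            scores = [
                dsc(predict(state, plan, img, sp), msk)["mean"]
                for img, msk, sp in val_sets[name]
            ]
            per_center[name] = float(np.mean(scores))
        dsc_by_mode[mode] = per_center
        logs[mode] = result.logs
        if mode == "local":
            local_models = [(result.states[n], result.plans[n]) for n in names]

    if local_models is None:
        raise ValueError("cross-center matrix requires the 'local' mode")
    matrix = cross_center_matrix(local_models, [val_sets[n] for n in names])
    return BenchmarkResult(
        center_names=names, dsc_by_mode=dsc_by_mode, matrix=matrix, logs=logs
    )


def run_benchmark_seeds(
    seeds: list[int], **kwargs
) -> tuple[dict, np.ndarray, list[str]]:
    """Average benchmark results over several seeds.

    Returns ``(mean_dsc_by_mode, mean_matrix, center_names)`` where the
    DSC dict maps mode -> center -> seed-averaged held-out DSC.
    """
    results = [run_benchmark(s, **kwargs) for s in seeds]
    names = results[0].center_names
    modes = list(results[0].dsc_by_mode)
    mean_dsc = {
        mode: {
            name: float(np.mean([r.dsc_by_mode[mode][name] for r in results]))
            for name in names
        }
        for mode in modes
    }
    mean_matrix = np.mean([r.matrix for r in results], axis=0)
    return mean_dsc, mean_matrix, names
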