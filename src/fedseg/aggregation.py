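"""Layer matching and (asymmetric) federated averaging of model states.

Given the clients' state dictionaries, the layer matching function
returns the *compatibility set*: layers whose name identifier appears
with an identical parameter shape across clients. Those layers are
averaged with client weights restricted to the contributing clients and
renormalized; all other layers stay local. Classical FedAvg is the
degenerate case where every layer is compatible.

Two matching readings are exposed:

* ``strict`` (default): a layer qualifies only if present in *every*
  client with one shape.
* ``partial``: a layer qualifies if at least ``min_clients`` clients hold
  it with one shape; the per-layer contributor set is recorded and the
  weights are renormalized over it.

Summation runs in ascending client order so results are bitwise
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from fedseg.model import ModelState

WeightMode = Literal["proportional", "equal_center"]


@dataclass
class AggregationWeights:
    """Per-client aggregation weights.

    ``proportional`` weights are proportional to client case counts (the
    default federated convention); ``equal_center`` gives every client the
    same weight regardless of dataset size.
    """

    mode: WeightMode
    values: tuple[float, ...]

    @classmethod
    def from_case_counts(cls, mode: WeightMode, n_cases: Sequence[int]) -> "AggregationWeights":
        if mode == "equal_center":
            raw = [1.0] * len(n_cases)
        elif mode == "proportional":
            raw = [float(n) for n in n_cases]
        else:
            raise ValueError(f"unknown weighting mode: {mode!r}")
        total = sum(raw)
        if total <= 0:
            raise ValueError("weights must have positive sum")
        return cls(mode=mode, values=tuple(w / total for w in raw))

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.values):
            raise ValueError("weights must be non-negative")


@dataclass
class CompatibleLayerSet:
    """The set C of aggregatable layers with per-layer contributor sets."""

    layers: "dict[str, tuple[int, ...]]"  # name -> sorted contributing client indices
    mode: str = "strict"

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __len__(self) -> int:
        return len(self.layers)

    def names(self) -> list[str]:
        return list(self.layers)


def compatible_layers(
    states: Sequence[ModelState],
    *,
    mode: Literal["strict", "partial"] = "strict",
    min_clients: int = 2,
) -> CompatibleLayerSet:
    """Compute the compatibility set over the clients' state dictionaries.

    In strict mode a name with any shape disagreement is excluded. In
    partial mode the holders are grouped by shape and the strictly
    largest group is aggregated if it has at least ``min_clients``
    members (a tie between shape groups excludes the layer — there is no
    principled winner). An empty result is valid (aggregation then
    degenerates to local training).
    """
    if len(states) < 2:
        raise ValueError("need at least two states")
    # name -> shape -> client indices holding that shape
    by_shape: dict[str, dict[tuple[int, ...], list[int]]] = {}
    for k, st in enumerate(states):
        for name, arr in st.params.items():
            by_shape.setdefault(name, {}).setdefault(tuple(arr.shape), []).append(k)
    layers: dict[str, tuple[int, ...]] = {}
    for name, groups in by_shape.items():
        if mode == "strict":
            if len(groups) == 1:
                (ks,) = groups.values()
                if len(ks) == len(states):
                    layers[name] = tuple(ks)
        elif mode == "partial":
            sizes = sorted((len(ks) for ks in groups.values()), reverse=True)
            if sizes[0] >= min_clients and (len(sizes) == 1 or sizes[0] > sizes[1]):
                ks = max(groups.values(), key=len)
                layers[name] = tuple(sorted(ks))
        else:
            raise ValueError(f"unknown matching mode: {mode!r}")
    return CompatibleLayerSet(layers=layers, mode=mode)


def aggregate_states(
    states: Sequence[ModelState],
    weights: AggregationWeights,
    layers: CompatibleLayerSet,
) -> "dict[str, np.ndarray]":
    """Weighted average of each compatible layer over its contributors.

    Weights are restricted to the layer's contributor set and
    renormalized to sum to one, so uniform weights reproduce the plain
    mean over contributing clients.
    """
    if len(weights.values) != len(states):
        raise ValueError("one weight per state required")
    agg: dict[str, np.ndarray] = {}
    for name, ks in layers.layers.items():
        for k in ks:
            if name not in states[k].params:
                raise ValueError(f"inconsistent compatibility set: {name} missing from client {k}")
        wsum = sum(weights.values[k] for k in ks)
        if wsum <= 0:
            raise ValueError(f"zero total weight for layer {name}")
        acc = np.zeros_like(states[ks[0]].params[name], dtype=np.float64)
        for k in sorted(ks):
            acc += (weights.values[k] / wsum) * states[k].params[name].astype(np.float64)
        agg[name] = acc.astype(states[ks[0]].params[name].dtype)
    return agg


def apply_update(local: ModelState, shared: "dict[str, np.ndarray]") -> ModelState:
    """Write the aggregated layers into a copy of the local state.

    Layers outside the shared set are bitwise unchanged; metadata
    (including the epoch counter) is preserved.
    """
    out = local.copy()
    for name, arr in shared.items():
        if name not in out.params:
            raise ValueError(f"stale compatibility set: {name} not in local state")
        if out.params[name].shape != arr.shape:
            raise ValueError(f"stale compatibility set: shape clash on {name}")
        out.params[name] = arr.copy()
    return out


def client_update(
    shared: "dict[str, np.ndarray]",
    layers: CompatibleLayerSet,
    client_index: int,
) -> "dict[str, np.ndarray]":
    """Restrict aggregated layers to those a given client contributed to.

    Under partial matching a client may lack a shared layer entirely or
    hold it with a different shape; only contributor layers may be written
    back into that client's state."""
    return {
        name: arr
        for name, arr in shared.items()
        if client_index in layers.layers.get(name, ())
    }


def fedavg(states: Sequence[ModelState], weights: AggregationWeights) -> ModelState:
    """Classical federated averaging; requires identical architectures."""
    ref = states[0].shapes()
    for st in states[1:]:
        if st.shapes() != ref:
            raise ValueError("architecture mismatch: fedavg requires identical models")
    layers = CompatibleLayerSet(
        layers={name: tuple(range(len(states))) for name in ref}, mode="strict"
    )
    agg = aggregate_states(states, weights, layers)
    out = states[0].copy()
    for name in out.params:
        out.params[name] = agg[name]
    return out
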