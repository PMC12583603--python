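"""Versioned readers/writers for exchanged artifacts.

Fingerprints and plans are canonical JSON (sorted keys, compact
separators), so equal objects produce byte-equal files. Checkpoints are
NumPy ``.npz`` archives holding the ordered parameter map plus a JSON
metadata entry with a SHA-256 checksum that is verified on read.
"""

from __future__ import annotations

import hashlib
import json
import os
from collections import OrderedDict
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict

from fedseg.fingerprint import DatasetFingerprint
from fedseg.model import ModelState
from fedseg.planner import TrainingPlan

FINGERPRINT_VERSION = 1
CHECKPOINT_VERSION = 1


def canonical_json(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))


# ------------------------------------------------------------ fingerprint


def fingerprint_to_dict(fp: DatasetFingerprint) -> dict:
    d = {
        "fingerprint_version": FINGERPRINT_VERSION,
        "dimensionality": fp.dimensionality,
        "n_cases": fp.n_cases,
        "shapes_after_crop": [list(s) for s in fp.shapes_after_crop],
        "spacings": [list(s) for s in fp.spacings],
        "intensity": None,
    }
    if fp.intensity_summary is not None:
        d["intensity"] = {
            "summary": fp.intensity_summary,
            "samples": [float(v) for v in np.asarray(fp.intensity_samples, dtype=np.float32)],
        }
    return d


def fingerprint_from_dict(d: dict) -> DatasetFingerprint:
    if d.get("fingerprint_version") != FINGERPRINT_VERSION:
        raise ValueError(f"unsupported fingerprint version: {d.get('fingerprint_version')!r}")
    intensity = d.get("intensity")
    return DatasetFingerprint(
        shapes_after_crop=[tuple(int(v) for v in s) for s in d["shapes_after_crop"]],
        spacings=[tuple(float(v) for v in s) for s in d["spacings"]],
        intensity_summary=None if intensity is None else dict(intensity["summary"]),
        n_cases=int(d["n_cases"]),
        dimensionality=int(d["dimensionality"]),
        intensity_samples=None
        if intensity is None
        else np.asarray(intensity["samples"], dtype=np.float32),
    )


def write_fingerprint(fp: DatasetFingerprint, path: str | os.PathLike) -> None:
    Path(path).write_text(canonical_json(fingerprint_to_dict(fp)))


def read_fingerprint(path: str | os.PathLike) -> DatasetFingerprint:
    return fingerprint_from_dict(json.loads(Path(path).read_text()))


# ------------------------------------------------------------------ plan


def write_plan(plan: TrainingPlan, path: str | os.PathLike) -> None:
    Path(path).write_text(canonical_json(plan.to_dict()))


def read_plan(path: str | os.PathLike) -> TrainingPlan:
    return TrainingPlan.from_dict(json.loads(Path(path).read_text()))


# ------------------------------------------------------------ checkpoint


def _state_checksum(params: "OrderedDict[str, np.ndarray]") -> str:
    h = hashlib.sha256()
    for name in sorted(params):
        arr = np.ascontiguousarray(params[name])
        h.update(name.encode())
        h.update(str(arr.shape).encode())
        h.update(str(arr.dtype).encode())
        h.update(arr.tobytes())
    return h.hexdigest()


def write_checkpoint(state: ModelState, path: str | os.PathLike) -> None:
    meta = {
        "checkpoint_version": CHECKPOINT_VERSION,
        "meta": state.meta,
        "layer_order": list(state.params),
        "checksum": _state_checksum(state.params),
    }
    arrays = dict(state.params)
    arrays["__meta__"] = np.frombuffer(canonical_json(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def read_checkpoint(path: str | os.PathLike) -> ModelState:
    with np.load(path) as npz:
        meta_raw = bytes(npz["__meta__"].tobytes()).decode()
        meta = json.loads(meta_raw)
        if meta.get("checkpoint_version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"unsupported checkpoint version: {meta.get('checkpoint_version')!r}; "
                "no migration path"
            )
        params = OrderedDict((name, npz[name]) for name in meta["layer_order"])
    if _state_checksum(params) != meta["checksum"]:
        raise ValueError("checkpoint checksum mismatch: file is corrupt or tampered")
    return ModelState(params=params, meta=meta["meta"])


# ------------------------------------------------------------ run config


class RunConfig(BaseModel):
    """Schema-validated training-run configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    mode: Literal["local", "centralized", "ffe", "asymfedavg"]
    weighting: Literal["proportional", "equal_center"] = "proportional"
    n_rounds: int = 30
    epochs_per_round: int = 1
    seed: int = 0
    data_dirs: list[str]
    out_dir: str = "runs"
    partial_matching: bool = False
    # resource budget
    max_patch_voxels: int = 64 * 64
    max_batch: int = 4
    max_stages: int | None = 3
    base_features: int = 8
    # hyperparameters
    lr: float = 0.03
    momentum: float = 0.95
    nesterov: bool = True
    weight_decay: float = 3e-5
    num_classes: int = 2
    iters_per_epoch: int | None = None


def read_run_config(path: str | os.PathLike) -> RunConfig:
    with open(path) as f:
        data = yaml.safe_load(f)
    return RunConfig(**data)


def write_run_config(cfg: RunConfig, path: str | os.PathLike) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))
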