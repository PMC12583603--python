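"""Self-configuring training-plan generation.

Maps a dataset fingerprint plus a per-client resource budget to a
:class:`TrainingPlan`: target spacing (per-axis median of case spacings),
median resampled shape, patch size, downsampling depth, channel schedule
and batch size. The rules follow the nnU-Net-style heuristic: halve each
patch axis until it would fall below a minimum bottleneck extent of 4,
which fixes the number of encoder stages; channels double per stage from
32 and are capped (512 for 2D, 320 for 3D).

Because the rules are deterministic functions of the fingerprint and the
budget, clients that share a budget and receive the same (global)
fingerprint derive byte-identical plans — the property FFE relies on.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

from fedseg.fingerprint import DatasetFingerprint

#: Minimum bottleneck feature-map extent per axis; one constant fixes the
#: stage counts (patch 256 -> 7 stages, 320 -> 7, 512 -> 8).
MIN_BOTTLENECK_EXTENT = 4
BASE_FEATURES = 32
FEATURE_CAP_2D = 512
FEATURE_CAP_3D = 320
#: Inverse-scaling reference for the batch-size heuristic: 12 samples at
#: a 512x512 patch.
BATCH_REF = 12
BATCH_REF_PATCH_VOXELS = 512 * 512
MIN_BATCH = 2


@dataclass(frozen=True)
class ResourceBudget:
    """Per-client capacity description.

    ``max_stages`` and ``base_features`` model memory-constrained
    clients: they cap network depth and width without changing the
    planning rules.
    """

    max_patch_voxels: int
    max_batch: int = 12
    dimensionality: int = 2
    max_stages: int | None = None
    base_features: int = BASE_FEATURES

    def __post_init__(self) -> None:
        if self.max_patch_voxels <= 0 or self.max_batch <= 0:
            raise ValueError("budget must be positive")
        if self.max_stages is not None and self.max_stages < 1:
            raise ValueError("max_stages must be >= 1")


@dataclass(frozen=True)
class TrainingPlan:
    target_spacing: tuple[float, ...]
    median_shape: tuple[int, ...]
    patch_size: tuple[int, ...]
    batch_size: int
    n_stages: int
    features_per_stage: tuple[int, ...]
    n_poolings_per_axis: tuple[int, ...]
    dimensionality: int
    normalization: str = "zscore"

    def __post_init__(self) -> None:
        if self.n_stages != len(self.features_per_stage):
            raise ValueError("n_stages must equal len(features_per_stage)")
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")
        for ax, p in zip(self.patch_size, self.n_poolings_per_axis):
            if ax % (2**p) != 0:
                raise ValueError("patch axis must be divisible by 2^poolings")
        feats = self.features_per_stage
        if any(feats[i] > feats[i + 1] for i in range(len(feats) - 1)):
            raise ValueError("features_per_stage must be non-decreasing")

    def to_dict(self) -> dict:
        return {
            "plan_version": 1,
            "target_spacing": list(self.target_spacing),
            "median_shape": list(self.median_shape),
            "patch_size": list(self.patch_size),
            "batch_size": self.batch_size,
            "n_stages": self.n_stages,
            "features_per_stage": list(self.features_per_stage),
            "n_poolings_per_axis": list(self.n_poolings_per_axis),
            "dimensionality": self.dimensionality,
            "normalization": self.normalization,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingPlan":
        if d.get("plan_version") != 1:
            raise ValueError(f"unsupported plan version: {d.get('plan_version')!r}")
        return cls(
            target_spacing=tuple(float(s) for s in d["target_spacing"]),
            median_shape=tuple(int(s) for s in d["median_shape"]),
            patch_size=tuple(int(s) for s in d["patch_size"]),
            batch_size=int(d["batch_size"]),
            n_stages=int(d["n_stages"]),
            features_per_stage=tuple(int(f) for f in d["features_per_stage"]),
            n_poolings_per_axis=tuple(int(p) for p in d["n_poolings_per_axis"]),
            dimensionality=int(d["dimensionality"]),
            normalization=str(d["normalization"]),
        )

    @property
    def plan_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(payload.encode()).hexdigest()


def lower_median(values: list[float]) -> float:
    """Median taking the lower of the two middle values for even counts.

    Integer-stable across platforms; no interpolation.
    """
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def _poolings(axis: int, max_stages: int | None) -> int:
    p = 0
    while axis // (2 ** (p + 1)) >= MIN_BOTTLENECK_EXTENT:
        p += 1
    if max_stages is not None:
        p = min(p, max_stages - 1)
    return p


def features_schedule(n_stages: int, dimensionality: int, base: int = BASE_FEATURES) -> tuple[int, ...]:
    cap = FEATURE_CAP_2D if dimensionality == 2 else FEATURE_CAP_3D
    return tuple(min(base * 2**i, cap) for i in range(n_stages))


def make_plan(fp: DatasetFingerprint, budget: ResourceBudget) -> TrainingPlan:
    """Derive a training plan from a fingerprint and a resource budget."""
    if fp.n_cases < 1:
        raise ValueError("no cases")
    dim = fp.dimensionality
    if budget.dimensionality != dim:
        raise ValueError(
            f"budget dimensionality {budget.dimensionality} != fingerprint {dim}"
        )
    if budget.max_patch_voxels < MIN_BOTTLENECK_EXTENT**dim:
        raise ValueError("budget infeasible")

    target_spacing = tuple(
        lower_median([sp[a] for sp in fp.spacings]) for a in range(dim)
    )
    # Per-case shapes rescaled into the target-spacing grid, then the
    # per-axis lower median, rounded half-up.
    median_shape = []
    for a in range(dim):
        rescaled = [
            sh[a] * sp[a] / target_spacing[a]
            for sh, sp in zip(fp.shapes_after_crop, fp.spacings)
        ]
        median_shape.append(max(MIN_BOTTLENECK_EXTENT, int(math.floor(lower_median(rescaled) + 0.5))))
    median_shape = tuple(median_shape)

    patch = list(median_shape)
    total = math.prod(patch)
    if total > budget.max_patch_voxels:
        f = (budget.max_patch_voxels / total) ** (1.0 / dim)
        patch = [max(MIN_BOTTLENECK_EXTENT, int(math.floor(ax * f))) for ax in patch]

    # Poolings and round-up interact: rounding an axis up to a multiple of
    # 2^p can cross a power-of-two boundary, so iterate to a fixed point.
    poolings = [0] * dim
    for _ in range(16):
        new_poolings = [_poolings(ax, budget.max_stages) for ax in patch]
        new_patch = [
            int(math.ceil(ax / 2**p) * 2**p) for ax, p in zip(patch, new_poolings)
        ]
        if new_poolings == poolings and new_patch == patch:
            break
        patch, poolings = new_patch, new_poolings

    n_stages = max(poolings) + 1
    feats = features_schedule(n_stages, dim, budget.base_features)
    batch = int(round(BATCH_REF * BATCH_REF_PATCH_VOXELS / math.prod(patch)))
    batch = max(MIN_BATCH, min(batch, budget.max_batch))

    return TrainingPlan(
        target_spacing=target_spacing,
        median_shape=median_shape,
        patch_size=tuple(patch),
        batch_size=batch,
        n_stages=n_stages,
        features_per_stage=feats,
        n_poolings_per_axis=tuple(poolings),
        dimensionality=dim,
    )
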