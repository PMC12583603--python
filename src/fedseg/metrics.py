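"""Segmentation metrics: Dice similarity coefficient and HD95.

HD95 is the 95th percentile (linear interpolation) of the pooled
symmetric surface-to-surface Euclidean distances, in physical units.
Surfaces are the boundary voxels of a mask — voxels with at least one
background face-neighbor (voxels at the array edge count); distances run
voxel-center to voxel-center, scaled by the spacing.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import ndimage


def _check_pair(pred: np.ndarray, ref: np.ndarray) -> None:
    if pred.shape != ref.shape:
        raise ValueError(f"incompatible masks: {pred.shape} vs {ref.shape}")


def dsc(pred: np.ndarray, ref: np.ndarray, *, labels: Sequence[int] | None = None) -> dict:
    """Dice coefficient per label plus the unweighted foreground mean.

    Conventions: both sides empty for a label -> 1.0; exactly one side
    empty -> 0.0.
    """
    _check_pair(pred, ref)
    if labels is None:
        labels = sorted(set(np.unique(pred)) | set(np.unique(ref)))
        labels = [int(l) for l in labels if l != 0]
        if not labels:
            labels = [1]
    per_label = {}
    for lab in labels:
        a = pred == lab
        b = ref == lab
        na, nb = int(a.sum()), int(b.sum())
        if na == 0 and nb == 0:
            per_label[lab] = 1.0
        elif na == 0 or nb == 0:
            per_label[lab] = 0.0
        else:
            per_label[lab] = 2.0 * int((a & b).sum()) / (na + nb)
    return {"per_label": per_label, "mean": float(np.mean(list(per_label.values())))}


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with >=1 background face-neighbor (array edges count)."""
    if not mask.any():
        return np.zeros_like(mask, dtype=bool)
    struct = ndimage.generate_binary_structure(mask.ndim, 1)
    eroded = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    return mask & ~eroded


def _surface_distances(
    a: np.ndarray, b: np.ndarray, spacing: Sequence[float]
) -> np.ndarray:
    """Directed distances from every boundary voxel of ``a`` to the
    nearest boundary voxel of ``b``."""
    bb = boundary_voxels(b)
    dt = ndimage.distance_transform_edt(~bb, sampling=spacing)
    return dt[boundary_voxels(a)]


def hd95(
    pred: np.ndarray,
    ref: np.ndarray,
    spacing: Sequence[float] | None = None,
    *,
    percentile: float = 95.0,
    empty_penalty: float | None = None,
) -> float:
    """95th-percentile symmetric surface distance for binary masks.

    Both masks empty -> 0.0. Exactly one empty -> ``empty_penalty``
    (default: the image diagonal in physical units, a documented choice
    for an undefined distance); use :func:`hd95_per_label` to see which
    values came from the penalty.
    """
    _check_pair(pred, ref)
    pred = pred.astype(bool)
    ref = ref.astype(bool)
    if spacing is None:
        spacing = (1.0,) * pred.ndim
    if not pred.any() and not ref.any():
        return 0.0
    if not pred.any() or not ref.any():
        if empty_penalty is None:
            empty_penalty = float(
                np.linalg.norm([s * d for s, d in zip(spacing, pred.shape)])
            )
        return empty_penalty
    pooled = np.concatenate(
        [_surface_distances(pred, ref, spacing), _surface_distances(ref, pred, spacing)]
    )
    return float(np.percentile(pooled, percentile))


def hd95_per_label(
    pred: np.ndarray,
    ref: np.ndarray,
    spacing: Sequence[float] | None = None,
    *,
    labels: Sequence[int] | None = None,
    empty_penalty: float | None = None,
) -> dict:
    """Per-label HD95 with the unweighted label mean; entries produced by
    the one-empty penalty are reported distinctly under ``penalized``."""
    _check_pair(pred, ref)
    if labels is None:
        labels = sorted(set(np.unique(pred)) | set(np.unique(ref)))
        labels = [int(l) for l in labels if l != 0]
        if not labels:
            labels = [1]
    per_label = {}
    penalized = []
    for lab in labels:
        a = pred == lab
        b = ref == lab
        if a.any() != b.any():
            penalized.append(lab)
        per_label[lab] = hd95(a, b, spacing, empty_penalty=empty_penalty)
    return {
        "per_label": per_label,
        "mean": float(np.mean(list(per_label.values()))),
        "penalized": penalized,
    }


def cross_center_matrix(
    models: Sequence[tuple],
    datasets: Sequence[Sequence[tuple]],
    *,
    num_classes: int = 2,
) -> np.ndarray:
    """Mean foreground DSC of every model on every center's cases.

    ``models``: per-center ``(state, plan)`` pairs (or bare callables
    ``f(image, spacing) -> mask``, useful for oracle predictors);
    ``datasets``: per-center lists of ``(image, mask, spacing)``. Entry
    ``(i, j)`` is model ``i`` evaluated on center ``j``; each case is
    resampled to the model's target spacing for inference and scored on
    its native grid.
    """
    from fedseg.training import predict

    mat = np.zeros((len(models), len(datasets)))
    for i, model in enumerate(models):
        for j, cases in enumerate(datasets):
            if not cases:
                raise ValueError(f"center {j} has no evaluation cases")
            scores = []
            for image, mask, spacing in cases:
                if spacing is None:
                    raise ValueError("cannot resample: spacing metadata missing")
                if callable(model):
                    pred = model(image, spacing)
                else:
                    state, plan = model
                    pred = predict(state, plan, image, spacing, num_classes=num_classes)
                scores.append(dsc(pred, mask)["mean"])
            mat[i, j] = float(np.mean(scores))
    return mat
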