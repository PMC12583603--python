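"""Dataset fingerprints and their federated aggregation (FFE).

A fingerprint summarizes one center's dataset by the spatial shape of
every case after cropping to the nonzero bounding box, the voxel spacing
of every case, and a pooled intensity summary. The federated global
fingerprint is formed by *concatenating* the per-center lists, so the
aggregate is usable anywhere a local fingerprint is — in particular as
input to the plan configurator, which is how every client ends up with
the same architecture under FFE.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Maximum number of intensity samples a fingerprint retains. Exact
#: percentile pooling over all voxels is not transmissible between
#: clients; a bounded subsample is.
INTENSITY_SAMPLE_CAP = 10_000


@dataclass
class CaseRecord:
    """Per-case contribution to a fingerprint."""

    shape_after_crop: tuple[int, ...]
    spacing: tuple[float, ...]
    intensity_sample: np.ndarray

    def __post_init__(self) -> None:
        if len(self.shape_after_crop) != len(self.spacing):
            raise ValueError("inconsistent case: shape and spacing lengths differ")
        if any(s < 1 for s in self.shape_after_crop):
            raise ValueError("inconsistent case: nonpositive shape entry")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("invalid metadata: nonpositive spacing")


@dataclass
class DatasetFingerprint:
    """Summary of one dataset (or, after aggregation, of a federation).

    ``intensity_samples`` is the retained subsample the summary was
    computed from; it is what gets pooled on aggregation. It can be
    omitted (``include_intensity=False`` at extraction) when a site does
    not wish to exchange intensity information.
    """

    shapes_after_crop: list[tuple[int, ...]]
    spacings: list[tuple[float, ...]]
    intensity_summary: dict | None
    n_cases: int
    dimensionality: int
    intensity_samples: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (len(self.shapes_after_crop) == len(self.spacings) == self.n_cases):
            raise ValueError("fingerprint list lengths must equal n_cases")
        if self.dimensionality not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")
        for v in list(self.shapes_after_crop) + list(self.spacings):
            if len(v) != self.dimensionality:
                raise ValueError("all fingerprint vectors must share dimensionality")
        if self.intensity_summary is not None:
            if self.intensity_summary["p00_5"] > self.intensity_summary["p99_5"]:
                raise ValueError("intensity percentiles out of order")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DatasetFingerprint):
            return NotImplemented
        same = (
            self.shapes_after_crop == other.shapes_after_crop
            and self.spacings == other.spacings
            and self.n_cases == other.n_cases
            and self.dimensionality == other.dimensionality
            and self.intensity_summary == other.intensity_summary
        )
        if not same:
            return False
        a, b = self.intensity_samples, other.intensity_samples
        if (a is None) != (b is None):
            return False
        return a is None or (a.shape == b.shape and bool(np.all(a == b)))


def nonzero_bounding_box(image: np.ndarray) -> tuple[slice, ...]:
    """Minimal axis-aligned bounding box of voxels with intensity != 0.

    An all-zero image falls back to the full array extent.
    """
    nz = image != 0
    if not nz.any():
        return tuple(slice(0, s) for s in image.shape)
    slices = []
    for ax in range(image.ndim):
        other = tuple(a for a in range(image.ndim) if a != ax)
        profile = nz.any(axis=other)
        idx = np.flatnonzero(profile)
        slices.append(slice(int(idx[0]), int(idx[-1]) + 1))
    return tuple(slices)


def _summary_from_samples(samples: np.ndarray) -> dict:
    samples = np.asarray(samples, dtype=np.float64)
    return {
        "mean": float(samples.mean()),
        "sd": float(samples.std()),
        "p00_5": float(np.percentile(samples, 0.5)),
        "p99_5": float(np.percentile(samples, 99.5)),
    }


def case_record(
    image: np.ndarray,
    mask: np.ndarray,
    spacing: Sequence[float],
    *,
    max_samples: int,
    rng: np.random.Generator,
) -> CaseRecord:
    """Crop a case to its nonzero bounding box and summarize it."""
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError(
            f"inconsistent case: image shape {image.shape} != mask shape {mask.shape}"
        )
    if any(s <= 0 for s in spacing):
        raise ValueError("invalid metadata: nonpositive spacing")
    box = nonzero_bounding_box(image)
    cropped = image[box]
    fg = cropped[cropped != 0]
    if fg.size == 0:
        fg = cropped.ravel()
    fg = fg.astype(np.float32, copy=False).ravel()
    if fg.size > max_samples:
        idx = rng.choice(fg.size, size=max_samples, replace=False)
        fg = fg[np.sort(idx)]
    return CaseRecord(
        shape_after_crop=tuple(int(s.stop - s.start) for s in box),
        spacing=tuple(float(s) for s in spacing),
        intensity_sample=fg,
    )


def fingerprint_from_cases(
    cases: Sequence[tuple[np.ndarray, np.ndarray, Sequence[float]]],
    *,
    intensity_cap: int = INTENSITY_SAMPLE_CAP,
    seed: int = 0,
    include_intensity: bool = True,
) -> DatasetFingerprint:
    """Build a fingerprint from in-memory ``(image, mask, spacing)`` triples."""
    if len(cases) == 0:
        raise ValueError("no cases")
    rng = np.random.default_rng(seed)
    per_case = max(1, intensity_cap // len(cases))
    records = [
        case_record(img, msk, sp, max_samples=per_case, rng=rng)
        for img, msk, sp in cases
    ]
    dim = len(records[0].shape_after_crop)
    samples = np.concatenate([r.intensity_sample for r in records])
    return DatasetFingerprint(
        shapes_after_crop=[r.shape_after_crop for r in records],
        spacings=[r.spacing for r in records],
        intensity_summary=_summary_from_samples(samples) if include_intensity else None,
        n_cases=len(records),
        dimensionality=dim,
        intensity_samples=samples if include_intensity else None,
    )


def extract_local_fingerprint(
    dataset_path: str | os.PathLike,
    *,
    intensity_cap: int = INTENSITY_SAMPLE_CAP,
    seed: int = 0,
    include_intensity: bool = True,
) -> DatasetFingerprint:
    """Extract the dataset fingerprint from a directory of NIfTI pairs."""
    from fedseg import nifti

    case_ids = nifti.list_cases(dataset_path)
    if not case_ids:
        raise ValueError(f"no cases in {dataset_path}")
    cases = [nifti.read_case(dataset_path, cid) for cid in case_ids]
    return fingerprint_from_cases(
        cases, intensity_cap=intensity_cap, seed=seed, include_intensity=include_intensity
    )


def aggregate_fingerprints(
    locals_: Sequence[DatasetFingerprint],
    *,
    intensity_cap: int = INTENSITY_SAMPLE_CAP,
    seed: int = 0,
) -> DatasetFingerprint:
    """Concatenate local fingerprints into the global federated fingerprint.

    ``shapes_after_crop`` and ``spacings`` are the ordered concatenations
    of the inputs' lists. The intensity summary is recomputed from the
    pooled retained samples (each case contributed an equal-size
    subsample at extraction, so plain pooling weights centers by case
    count); if the pool exceeds the cap it is subsampled deterministically.
    """
    if len(locals_) == 0:
        raise ValueError("no fingerprints")
    dims = {fp.dimensionality for fp in locals_}
    if len(dims) != 1:
        raise ValueError(f"dimensionality mismatch: {sorted(dims)}")
    shapes: list[tuple[int, ...]] = []
    spacings: list[tuple[float, ...]] = []
    for fp in locals_:
        shapes.extend(fp.shapes_after_crop)
        spacings.extend(fp.spacings)
    sample_arrays = [fp.intensity_samples for fp in locals_ if fp.intensity_samples is not None]
    if sample_arrays and len(sample_arrays) == len(locals_):
        pooled = np.concatenate(sample_arrays)
        if pooled.size > intensity_cap:
            rng = np.random.default_rng(seed)
            idx = rng.choice(pooled.size, size=intensity_cap, replace=False)
            pooled = pooled[np.sort(idx)]
        summary = _summary_from_samples(pooled)
    else:
        pooled = None
        summary = None
    return DatasetFingerprint(
        shapes_after_crop=shapes,
        spacings=spacings,
        intensity_summary=summary,
        n_cases=sum(fp.n_cases for fp in locals_),
        dimensionality=dims.pop(),
        intensity_samples=pooled,
    )
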