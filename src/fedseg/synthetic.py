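"""Synthetic multi-center segmentation data.

Each center draws grayscale 2D images containing a handful of smooth
elliptical lesions on a noisy background with a multiplicative low
frequency bias field. Lesion geometry is parameterized in millimeters,
so centers with different voxel spacings see genuinely different
resolutions of the same physical objects — the heterogeneity axis that
federated self-configuration has to cope with. Centers additionally
differ in matrix size, contrast-to-noise ratio and lesion size
distribution, emulating the cross-site variability of real multi-center
collections (2x spacing gaps, 2x matrix-size gaps, low- vs high-end
scanners).

Every case is fully determined by ``(spec.seed, case_index)``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

#: Minimum separation between foreground and background means, as a
#: multiple of the larger noise SD. Guards against specs that generate
#: unlearnable data.
CONTRAST_FLOOR = 0.5


@dataclass(frozen=True)
class CenterSpec:
    """Generative description of one synthetic center."""

    name: str
    shape_range: tuple[tuple[int, int], ...]  # (min, max) per axis, voxels
    spacing: tuple[float, ...]  # mm per voxel
    bg_mean: float = 0.0
    bg_sd: float = 0.5
    fg_mean: float = 1.0
    fg_sd: float = 0.5
    bias_amplitude: float = 0.25
    lesion_count: tuple[int, int] = (1, 3)
    lesion_radius_mm: tuple[float, float] = (8.0, 16.0)
    ellipticity: tuple[float, float] = (0.6, 1.0)
    n_labels: int = 1  # 1 = binary; 3 = nested three-structure variant
    n_cases: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        sd = max(self.bg_sd, self.fg_sd)
        if self.fg_mean - self.bg_mean < CONTRAST_FLOOR * max(sd, 1e-8):
            raise ValueError("foreground/background contrast below the floor")
        if self.n_labels not in (1, 3):
            raise ValueError("n_labels must be 1 or 3")


@dataclass
class SyntheticCase:
    image: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, ...]
    provenance: dict = field(default_factory=dict)


def _rasterize_ellipse(
    shape: tuple[int, int],
    spacing: tuple[float, float],
    center_mm: np.ndarray,
    radii_mm: np.ndarray,
    angle: float,
    scale: float = 1.0,
) -> np.ndarray:
    """Boolean mask of an ellipse given in physical (mm) coordinates."""
    grid = np.indices(shape).astype(np.float64)
    coords = [grid[a] * spacing[a] - center_mm[a] for a in range(2)]
    c, s = np.cos(angle), np.sin(angle)
    u = c * coords[0] + s * coords[1]
    v = -s * coords[0] + c * coords[1]
    r = radii_mm * scale
    return (u / r[0]) ** 2 + (v / r[1]) ** 2 <= 1.0


def generate_case(spec: CenterSpec, index: int) -> SyntheticCase:
    """Generate one case; deterministic in ``(spec.seed, index)``."""
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, index)))
    shape = tuple(int(rng.integers(lo, hi + 1)) for lo, hi in spec.shape_range)
    extent_mm = np.array([sh * sp for sh, sp in zip(shape, spec.spacing)])
    max_r = spec.lesion_radius_mm[1]
    if any(extent_mm < 2.0 * max_r + 2.0 * max(spec.spacing)):
        raise ValueError(
            f"spec infeasible: lesion radius {max_r} mm does not fit in a "
            f"{extent_mm.tolist()} mm field of view"
        )

    mask = np.zeros(shape, dtype=np.uint8)
    n_lesions = int(rng.integers(spec.lesion_count[0], spec.lesion_count[1] + 1))
    for _ in range(n_lesions):
        r = float(rng.uniform(*spec.lesion_radius_mm))
        e = float(rng.uniform(*spec.ellipticity))
        radii = np.array([r, r * e])
        angle = float(rng.uniform(0.0, np.pi))
        margin = radii.max()
        center = np.array(
            [rng.uniform(margin, ext - margin) for ext in extent_mm]
        )
        outer = _rasterize_ellipse(shape, spec.spacing, center, radii, angle)
        if spec.n_labels == 1:
            mask[outer] = 1
        else:  # nested three-structure variant (ring / mid / core)
            mid = _rasterize_ellipse(shape, spec.spacing, center, radii, angle, 0.7)
            core = _rasterize_ellipse(shape, spec.spacing, center, radii, angle, 0.4)
            mask[outer] = 1
            mask[mid] = 2
            mask[core] = 3

    image = spec.bg_mean + spec.bg_sd * rng.standard_normal(shape)
    fg = mask > 0
    # per-label intensity steps so the nested structures are separable
    offsets = spec.fg_mean + 0.3 * (spec.fg_mean - spec.bg_mean) * (
        mask.astype(np.float64) - 1
    )
    image[fg] = offsets[fg] + spec.fg_sd * rng.standard_normal(int(fg.sum()))

    if spec.bias_amplitude > 0:
        fieldn = ndimage.gaussian_filter(
            rng.standard_normal(shape), sigma=max(2.0, min(shape) / 4.0)
        )
        peak = float(np.abs(fieldn).max())
        if peak > 1e-12:
            image *= 1.0 + spec.bias_amplitude * fieldn / peak

    return SyntheticCase(
        image=image.astype(np.float32),
        mask=mask,
        spacing=spec.spacing,
        provenance={"center": spec.name, "index": index, "seed": spec.seed},
    )


def generate_center(
    spec: CenterSpec, out_dir: str | os.PathLike | None = None
) -> list[SyntheticCase]:
    """Generate all of a center's cases; optionally write NIfTI pairs."""
    cases = [generate_case(spec, i) for i in range(spec.n_cases)]
    if out_dir is not None:
        from fedseg import nifti

        for i, case in enumerate(cases):
            nifti.write_case(out_dir, f"{spec.name}_{i:03d}", case.image, case.mask, case.spacing)
    return cases


def expected_foreground_fraction(spec: CenterSpec, n_mc: int = 20000, seed: int = 12345) -> float:
    """Monte-Carlo estimate of the expected foreground fraction implied by
    the spec's lesion model (ellipse area over field of view), ignoring
    lesion overlap. An analytic cross-check for the generator."""
    rng = np.random.default_rng(seed)
    mean_shape = [np.mean(sr) for sr in spec.shape_range]
    fov = float(np.prod([sh * sp for sh, sp in zip(mean_shape, spec.spacing)]))
    r = rng.uniform(*spec.lesion_radius_mm, size=n_mc)
    e = rng.uniform(*spec.ellipticity, size=n_mc)
    area = np.pi * r * (r * e)
    mean_count = np.mean(spec.lesion_count)
    return float(mean_count * area.mean() / fov)


# ------------------------------------------------------------- benchmarks


def benchmark_specs(
    preset: str, *, seed: int = 0, n_cases: int = 25
) -> list[CenterSpec]:
    """Center specs for the named multi-center benchmark preset.

    ``homogeneous3``: three statistically identical centers (fixed matrix
    and spacing), so self-configuration yields identical plans.
    ``heterogeneous3``: two low-resolution centers and one high-resolution
    center with ~2x finer spacing, ~2x larger matrices and smaller
    lesions (a low/high-end device split).
    ``heterogeneous4``: four centers with a 2x spacing gap between the
    finest and the coarsest and one deliberately small center.
    """
    seeds = [int(np.random.SeedSequence((seed, i)).generate_state(1)[0] % 2**31) for i in range(4)]
    if preset == "homogeneous3":
        return [
            CenterSpec(
                name=f"center{i}",
                shape_range=((80, 80), (80, 80)),
                spacing=(1.0, 1.0),
                bg_sd=1.0, fg_sd=1.0, bias_amplitude=0.35,
                lesion_count=(1, 3), lesion_radius_mm=(6.0, 16.0),
                n_cases=n_cases,
                seed=seeds[i],
            )
            for i in range(3)
        ]
    if preset == "heterogeneous3":
        return [
            CenterSpec(
                name="siteA_lowres",
                shape_range=((64, 80), (64, 80)),
                spacing=(1.0, 1.0),
                bg_mean=0.0, bg_sd=1.0, fg_mean=1.0, fg_sd=1.0,
                bias_amplitude=0.35,
                lesion_count=(1, 3), lesion_radius_mm=(6.0, 16.0),
                n_cases=n_cases, seed=seeds[0],
            ),
            CenterSpec(
                name="siteB_lowres",
                shape_range=((72, 96), (72, 96)),
                spacing=(0.9, 0.9),
                bg_mean=0.1, bg_sd=1.2, fg_mean=1.1, fg_sd=1.2,
                bias_amplitude=0.4,
                lesion_count=(1, 3), lesion_radius_mm=(6.0, 16.0),
                n_cases=n_cases, seed=seeds[1],
            ),
            CenterSpec(
                name="siteC_highres",
                shape_range=((128, 160), (128, 160)),
                spacing=(0.5, 0.5),
                bg_mean=0.0, bg_sd=0.9, fg_mean=1.0, fg_sd=0.9,
                bias_amplitude=0.3,
                lesion_count=(1, 4), lesion_radius_mm=(4.0, 9.0),
                n_cases=n_cases, seed=seeds[2],
            ),
        ]
    if preset == "heterogeneous4":
        return [
            CenterSpec(
                name="siteA", shape_range=((80, 112), (80, 112)), spacing=(1.4, 1.4),
                bg_sd=1.0, fg_sd=1.0, bias_amplitude=0.35,
                lesion_radius_mm=(10.0, 20.0),
                n_cases=n_cases, seed=seeds[0],
            ),
            CenterSpec(
                name="siteB", shape_range=((80, 112), (80, 112)), spacing=(1.3, 1.3),
                bg_mean=0.1, bg_sd=1.1, fg_mean=1.1, fg_sd=1.1, bias_amplitude=0.4,
                lesion_radius_mm=(10.0, 20.0), n_cases=n_cases, seed=seeds[1],
            ),
            CenterSpec(
                name="siteC_fine", shape_range=((128, 160), (128, 160)), spacing=(0.7, 0.7),
                bg_sd=0.9, fg_sd=0.9, bias_amplitude=0.3,
                lesion_radius_mm=(8.0, 14.0),
                n_cases=n_cases, seed=seeds[2],
            ),
            CenterSpec(
                name="siteD_small", shape_range=((64, 96), (64, 96)), spacing=(1.4, 1.4),
                bg_sd=1.0, fg_sd=1.0, bias_amplitude=0.35,
                lesion_radius_mm=(10.0, 18.0),
                n_cases=max(4, n_cases // 2), seed=seeds[3],
            ),
        ]
    raise ValueError(f"unknown preset: {preset!r}")


def make_benchmark(
    preset: str,
    out_dir: str | os.PathLike | None = None,
    *,
    seed: int = 0,
    n_cases: int = 25,
) -> dict[str, list[SyntheticCase]]:
    """Generate a per-center benchmark dataset.

    When ``out_dir`` is given, per-center subdirectories of NIfTI pairs
    and a ``manifest.json`` with the specs are written.
    """
    specs = benchmark_specs(preset, seed=seed, n_cases=n_cases)
    data: dict[str, list[SyntheticCase]] = {}
    for spec in specs:
        sub = None if out_dir is None else Path(out_dir) / spec.name
        data[spec.name] = generate_center(spec, sub)
    if out_dir is not None:
        manifest = {
            "preset": preset,
            "seed": seed,
            "centers": [asdict(s) for s in specs],
        }
        Path(out_dir, "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
    return data
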