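"""NIfTI case I/O.

A *case* is an image/mask pair stored as ``<case>_img.nii.gz`` and
``<case>_seg.nii.gz`` with voxel spacing carried in the header zooms.
2D images are stored as single-slice volumes (H, W, 1) and read back as
2D arrays with a 2-vector spacing.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

IMG_SUFFIXES = ("_img.nii.gz", "_img.nii")
SEG_SUFFIXES = ("_seg.nii.gz", "_seg.nii")


def _spacing_affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    for i, s in enumerate(spacing[:3]):
        aff[i, i] = float(s)
    return aff


def write_case(
    directory: str | os.PathLike,
    case_id: str,
    image: np.ndarray,
    mask: np.ndarray,
    spacing: Sequence[float],
) -> tuple[Path, Path]:
    """Write an image/mask pair as NIfTI; returns the two paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    image = np.asarray(image)
    mask = np.asarray(mask)
    spacing = [float(s) for s in spacing]
    if image.ndim == 2:
        image = image[:, :, None]
        mask = mask[:, :, None]
        spacing = spacing + [1.0]
    if image.ndim != 3:
        raise ValueError(f"expected 2D or 3D image, got ndim={image.ndim}")
    aff = _spacing_affine(spacing)
    img_nii = nib.Nifti1Image(image.astype(np.float32), aff)
    img_nii.header.set_zooms(spacing)
    seg_nii = nib.Nifti1Image(mask.astype(np.uint8), aff)
    seg_nii.header.set_zooms(spacing)
    img_path = directory / f"{case_id}_img.nii.gz"
    seg_path = directory / f"{case_id}_seg.nii.gz"
    nib.save(img_nii, img_path)
    nib.save(seg_nii, seg_path)
    return img_path, seg_path


def _read_volume(path: Path) -> tuple[np.ndarray, tuple[float, ...]]:
    try:
        nii = nib.load(str(path))
        data = np.asanyarray(nii.dataobj)
        zooms = tuple(float(z) for z in nii.header.get_zooms()[: data.ndim])
    except Exception as exc:  # pragma: no cover - nibabel error classes vary
        raise ValueError(f"malformed header or unreadable file: {path}: {exc}") from exc
    return data, zooms


def read_case(
    directory: str | os.PathLike, case_id: str
) -> tuple[np.ndarray, np.ndarray, tuple[float, ...]]:
    """Read an image/mask pair; returns ``(image, mask, spacing)``.

    Single-slice third axes are squeezed so that 2D cases round-trip as
    2D arrays.
    """
    directory = Path(directory)
    img_path = seg_path = None
    for suf in IMG_SUFFIXES:
        if (directory / f"{case_id}{suf}").exists():
            img_path = directory / f"{case_id}{suf}"
            break
    for suf in SEG_SUFFIXES:
        if (directory / f"{case_id}{suf}").exists():
            seg_path = directory / f"{case_id}{suf}"
            break
    if img_path is None or seg_path is None:
        raise FileNotFoundError(f"missing pair member for case {case_id!r} in {directory}")
    image, spacing = _read_volume(img_path)
    mask, _ = _read_volume(seg_path)
    if image.ndim == 3 and image.shape[2] == 1:
        image = image[:, :, 0]
        mask = mask[:, :, 0] if mask.ndim == 3 else mask
        spacing = spacing[:2]
    return np.asarray(image), np.asarray(mask), spacing


def list_cases(directory: str | os.PathLike) -> list[str]:
    """Case ids in a directory, sorted, determined by ``*_img.nii[.gz]`` files."""
    directory = Path(directory)
    ids = set()
    for p in directory.iterdir() if directory.exists() else []:
        name = p.name
        for suf in IMG_SUFFIXES:
            if name.endswith(suf):
                ids.add(name[: -len(suf)])
    return sorted(ids)
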