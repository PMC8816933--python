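"""Voxel volume containers and NIfTI-1 I/O.

Two thin wrappers around 3-D numpy arrays are used throughout the package:
:class:`LabelVolume` for integer masks / label maps and :class:`ScalarVolume`
for real-valued maps (distances, normalized distances).  Both carry physical
voxel spacing in millimetres; all computations happen in voxel space with
spacing-aware metrics, and the affine (if any) is carried through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np

__all__ = [
    "LabelVolume",
    "ScalarVolume",
    "load_label_volume",
    "load_scalar_volume",
    "save_volume",
]

Spacing = tuple[float, float, float]


def _check_spacing(spacing) -> Spacing:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive reals, got {spacing!r}")
    return spacing


@dataclass
class LabelVolume:
    """3-D integer grid with physical spacing (mm per voxel axis)."""

    data: np.ndarray
    spacing: Spacing
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.array_equal(self.data, np.round(self.data)):
                raise ValueError("label volume requires integer values")
            self.data = self.data.astype(np.int32)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in mm^3."""
        return float(np.prod(self.spacing))

    def count(self) -> int:
        return int(np.count_nonzero(self.data))

    def volume_mm3(self) -> float:
        return self.count() * self.voxel_volume

    def as_bool(self) -> np.ndarray:
        return self.data != 0


@dataclass
class ScalarVolume:
    """3-D float grid with physical spacing (mm per voxel axis)."""

    data: np.ndarray
    spacing: Spacing
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


VolumeLike = Union[LabelVolume, ScalarVolume]


def _spacing_from_header(img: nib.Nifti1Image) -> Spacing:
    zooms = img.header.get_zooms()[:3]
    return _check_spacing(zooms)


def load_label_volume(path: str | Path) -> LabelVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return LabelVolume(np.round(data).astype(np.int32), _spacing_from_header(img), affine=img.affine)


def load_scalar_volume(path: str | Path) -> ScalarVolume:
    img = nib.load(str(path))
    return ScalarVolume(img.get_fdata(), _spacing_from_header(img), affine=img.affine)


def save_volume(vol: VolumeLike, path: str | Path) -> None:
    """Write a volume as NIfTI-1 with spacing encoded in the header zooms."""
    if vol.affine is not None:
        affine = vol.affine
    else:
        affine = np.diag(list(vol.spacing) + [1.0])
    if isinstance(vol, LabelVolume):
        data = vol.data.astype(np.int16 if vol.data.max(initial=0) < 2**15 else np.int32)
    else:
        data = vol.data.astype(np.float32)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def check_same_grid(*vols: VolumeLike) -> None:
    """Raise if the volumes disagree on shape or spacing (no resampling here)."""
    ref = vols[0]
    for v in vols[1:]:
        if v.shape != ref.shape:
            raise ValueError(f"shape mismatch: {v.shape} vs {ref.shape}")
        if not np.allclose(v.spacing, ref.spacing):
            raise ValueError(f"spacing mismatch: {v.spacing} vs {ref.spacing}")
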