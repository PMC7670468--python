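"""Core image containers: scalar volumes and segmentation mask sets.

Arrays are indexed (x, y, z) with the acquisition slices along the last
axis; ``spacing_mm`` gives the physical voxel size per axis in
millimetres. NIfTI round-trips use a diagonal affine built from the
spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "MaskSet", "load_volume", "load_mask"]


@dataclass
class ImageVolume:
    """A 3D scalar lattice with physical voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel intensities. Non-finite values are permitted only where a
        producer explicitly flags invalid voxels (e.g. ADC maps).
    spacing_mm : tuple of float
        Per-axis voxel size in millimetres, strictly positive.
    id : str
        Identifier, e.g. ``"case003_T2"``.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.values.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def with_values(self, values: np.ndarray, id: str | None = None) -> "ImageVolume":
        return ImageVolume(values, self.spacing_mm, self.id if id is None else id)

    def save(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), affine), str(path))


@dataclass
class MaskSet:
    """Binary uterus / conization-cavity masks plus the derived margin VOI.

    Invariants: ``cavity ⊆ uterus``; when built, ``margin_voi ⊆ uterus``
    and ``margin_voi ∩ cavity = ∅``. All masks share one grid.
    """

    uterus: np.ndarray
    cavity: np.ndarray
    spacing_mm: tuple[float, float, float]
    margin_voi: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.uterus = np.asarray(self.uterus, dtype=bool)
        self.cavity = np.asarray(self.cavity, dtype=bool)
        if self.uterus.shape != self.cavity.shape:
            raise ValueError("uterus and cavity masks must share one grid")
        if np.any(self.cavity & ~self.uterus):
            raise ValueError("cavity mask extends outside the uterus mask")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if self.margin_voi is not None:
            self.margin_voi = np.asarray(self.margin_voi, dtype=bool)
            if self.margin_voi.shape != self.uterus.shape:
                raise ValueError("margin VOI must share the mask grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.uterus.shape

    def copy(self) -> "MaskSet":
        return MaskSet(
            self.uterus.copy(),
            self.cavity.copy(),
            self.spacing_mm,
            None if self.margin_voi is None else self.margin_voi.copy(),
        )

    def with_voi(self, voi: np.ndarray) -> "MaskSet":
        return replace(self, margin_voi=np.asarray(voi, dtype=bool))

    def save(self, directory: str | Path, prefix: str = "") -> None:
        directory = Path(directory)
        affine = np.diag(list(self.spacing_mm) + [1.0])
        for name, mask in [("uterus", self.uterus), ("cavity", self.cavity), ("margin_voi", self.margin_voi)]:
            if mask is None:
                continue
            img = nib.Nifti1Image(mask.astype(np.uint8), affine)
            nib.save(img, str(directory / f"{prefix}{name}.nii.gz"))


def _spacing_from(img: nib.Nifti1Image) -> tuple[float, float, float]:
    return tuple(float(z) for z in img.header.get_zooms()[:3])


def load_volume(path: str | Path, id: str = "") -> ImageVolume:
    img = nib.load(str(path))
    return ImageVolume(np.asanyarray(img.dataobj, dtype=np.float64), _spacing_from(img), id or Path(path).stem)


def load_mask(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj) > 0.5, _spacing_from(img)
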