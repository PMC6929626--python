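"""Lightweight volumetric container shared by the MR and PET stages.

All 3D images in the pipeline travel as :class:`ImageVolume`: a scalar grid
plus voxel size, world origin and a units tag.  Volumes are persisted as
NIfTI-1 with the voxel size carried in the affine, which keeps them readable
by any neuroimaging viewer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "load_nifti", "save_nifti"]


@dataclass
class ImageVolume:
    """A 3D scalar grid with geometry metadata.

    Parameters
    ----------
    data:
        3D array of voxel values.
    voxel_size_mm:
        Edge lengths of one voxel in millimetres, (dx, dy, dz).
    origin_mm:
        World coordinate of the centre of voxel (0, 0, 0).
    units:
        Free-form tag describing the physical units of ``data``
        (e.g. ``"kBq/mL"``, ``"s"``, ``"%ID/mL"``, ``"mM"``).
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    units: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"ImageVolume requires a 3D array, got shape {self.data.shape}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world (mm) affine (axis-aligned grid)."""
        aff = np.diag([*self.voxel_size_mm, 1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 mL = 1000 mm^3)."""
        return float(np.prod(self.voxel_size_mm)) / 1000.0

    def with_data(self, data: np.ndarray, units: str | None = None) -> "ImageVolume":
        """Same geometry, new values."""
        out = replace(self, data=np.asarray(data))
        if units is not None:
            out.units = units
        return out

    def same_grid(self, other: "ImageVolume", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.voxel_size_mm, other.voxel_size_mm, atol=atol
        ) and np.allclose(self.origin_mm, other.origin_mm, atol=atol)


def save_nifti(vol: ImageVolume, path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), vol.affine)
    img.header.set_zooms(vol.voxel_size_mm)
    if vol.units:
        img.header["descrip"] = vol.units.encode()[:79]
    nib.save(img, str(path))


def load_nifti(path, units: str = "") -> ImageVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D NIfTI, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    tag = units or img.header["descrip"].tobytes().split(b"\x00")[0].decode(errors="ignore")
    return ImageVolume(data=data, voxel_size_mm=zooms, origin_mm=origin, units=tag)
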