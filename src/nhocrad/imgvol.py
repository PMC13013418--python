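"""Volume and mask data model with NIfTI I/O and geometric resampling.

Coordinate convention
---------------------
Voxel indices are 0-based and a voxel's physical centre is
``origin + index * spacing`` (node-centred).  All distances downstream
(annulus construction, hotspot-to-centroid) are Euclidean distances between
voxel centres in millimetres.  Volumes are reoriented to canonical (RAS)
axis order on load so that NIfTI affine ambiguity never enters a distance
computation; axis 0 is x, axis 1 is y, axis 2 is z.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

AXIS_ORDER = "RAS"
_GEOM_TOL_MM = 1e-4


@dataclass(frozen=True)
class VolumeGeometry:
    """Physical geometry of a regular 3-D grid.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis (x, y, z).
    spacing : tuple of float
        Voxel edge lengths in mm per axis; all components > 0.
    origin : tuple of float
        Physical position (mm) of the centre of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = AXIS_ORDER

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive mm values, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical field of view along each axis (shape × spacing)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def matches(self, other: "VolumeGeometry", tol_mm: float = _GEOM_TOL_MM) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol_mm for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol_mm for a, b in zip(self.origin, other.origin))
        )

    def affine(self) -> np.ndarray:
        """4×4 voxel-index → mm affine under the node-centred convention."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff


@dataclass
class ScalarVolume:
    """A 3-D intensity grid: SUV for PET, Hounsfield units for CT."""

    geometry: VolumeGeometry
    values: np.ndarray
    modality: Literal["PET", "CT"] = "PET"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )
        n_bad = int(np.count_nonzero(~np.isfinite(self.values)))
        if n_bad:
            raise ValueError(f"{n_bad} non-finite voxel(s) in {self.modality} volume")
        if self.modality == "PET" and float(self.values.min()) < 0:
            raise ValueError("PET volume contains negative SUV values")


@dataclass
class BinaryMask:
    """A {0,1}-valued VOI mask sharing a volume's geometry."""

    geometry: VolumeGeometry
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        vals = np.asarray(self.values)
        if vals.shape != self.geometry.shape:
            raise ValueError(
                f"mask shape {vals.shape} != geometry shape {self.geometry.shape}"
            )
        if vals.dtype != bool:
            uniq = np.unique(vals)
            if not np.all(np.isin(uniq, (0, 1))):
                logger.warning(
                    "mask %r not strictly {0,1}: thresholding values > 0.5", self.label
                )
            vals = vals > 0.5
        self.values = vals

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.values))

    @property
    def volume_ml(self) -> float:
        return self.n_voxels * self.geometry.voxel_volume_mm3 / 1000.0


def derived_volume(template: ScalarVolume, values: np.ndarray) -> ScalarVolume:
    """A ScalarVolume of filter responses on a template's grid.

    Bypasses the PET non-negativity invariant: wavelet/LoG responses are
    signed even when derived from SUV images.
    """
    out = ScalarVolume.__new__(ScalarVolume)
    out.geometry = template.geometry
    out.values = np.asarray(values, dtype=np.float64)
    out.modality = template.modality
    if out.values.shape != template.geometry.shape:
        raise ValueError("derived values do not match template geometry")
    return out


def _geometry_from_nifti(img: nib.Nifti1Image) -> VolumeGeometry:
    img = nib.as_closest_canonical(img)
    zooms = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3]
    return VolumeGeometry(
        shape=img.shape[:3], spacing=tuple(float(z) for z in zooms),
        origin=tuple(float(o) for o in origin),
    )


def read_volume(path: str | Path, modality: Literal["PET", "CT"] = "PET") -> ScalarVolume:
    """Read a 3-D NIfTI volume; geometry is taken from the header.

    Non-finite voxels are rejected (not zeroed): a NaN SUV silently set to
    zero would corrupt SUVmax and every metric downstream.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if len([d for d in img.shape if d > 1]) > 3 or img.ndim != 3:
        raise ValueError(f"expected 3-D volume, got shape {img.shape}")
    canon = nib.as_closest_canonical(img)
    data = np.asarray(canon.dataobj, dtype=np.float64)
    geom = _geometry_from_nifti(img)
    return ScalarVolume(geometry=geom, values=data, modality=modality)


def read_mask(path: str | Path, label: str = "") -> BinaryMask:
    """Read a binary mask NIfTI; values > 0.5 map to 1 (logged if non-binary)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"expected 3-D mask, got shape {img.shape}")
    canon = nib.as_closest_canonical(img)
    data = np.asarray(canon.dataobj, dtype=np.float64)
    geom = _geometry_from_nifti(img)
    return BinaryMask(geometry=geom, values=data, label=label or path.stem)


def write_volume(vol: ScalarVolume | BinaryMask, path: str | Path) -> None:
    """Write a volume or mask to NIfTI preserving geometry."""
    data = vol.values
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(np.asarray(data), vol.geometry.affine())
    img.header.set_zooms(vol.geometry.spacing)
    nib.save(img, str(path))


def check_same_geometry(a, b, tol_mm: float = _GEOM_TOL_MM) -> bool:
    """True iff the two grids agree in shape, spacing and origin (1e-4 mm)."""
    return a.geometry.matches(b.geometry, tol_mm)


def require_same_geometry(a, b) -> None:
    if not check_same_geometry(a, b):
        raise ValueError(
            f"geometry mismatch: {a.geometry.shape}@{a.geometry.spacing} vs "
            f"{b.geometry.shape}@{b.geometry.spacing}"
        )


def resample(
    v: ScalarVolume | BinaryMask,
    target_spacing: Sequence[float],
    interpolation: Literal["linear", "nearest"] = "linear",
) -> ScalarVolume | BinaryMask:
    """Resample a volume to a new voxel spacing (e.g. the 3×3×5 mm analysis grid).

    The output grid keeps the input origin; output shape is
    ``ceil(extent / target_spacing)`` so the physical field of view is
    preserved to within one output voxel.  Intensities use linear
    interpolation, masks nearest-neighbour.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    geom = v.geometry
    if interpolation == "linear" and any(n == 1 for n in geom.shape):
        logger.warning("single-voxel axis: falling back to nearest-neighbour")
        interpolation = "nearest"

    new_shape = tuple(
        max(1, math.ceil(e / t)) for e, t in zip(geom.extent_mm, target_spacing)
    )
    new_geom = VolumeGeometry(shape=new_shape, spacing=target_spacing, origin=geom.origin)

    # output voxel centre j*t maps to input continuous index j*t/s
    grids = [
        np.arange(n) * t / s for n, t, s in zip(new_shape, target_spacing, geom.spacing)
    ]
    coords = np.meshgrid(*grids, indexing="ij")
    order = 1 if interpolation == "linear" else 0
    is_mask = isinstance(v, BinaryMask)
    src = v.values.astype(np.float64)
    out = ndimage.map_coordinates(src, np.stack(coords), order=order, mode="nearest")
    if is_mask:
        return BinaryMask(geometry=new_geom, values=out > 0.5, label=v.label)
    return ScalarVolume(geometry=new_geom, values=out, modality=v.modality)


def voxel_centres(m: BinaryMask) -> np.ndarray:
    """Physical centres (mm) of all set voxels, one row per voxel.

    Empty mask → empty (0, 3) array.
    """
    idx = np.argwhere(m.values)
    if idx.size == 0:
        return np.empty((0, 3))
    spacing = np.asarray(m.geometry.spacing)
    origin = np.asarray(m.geometry.origin)
    return origin + idx * spacing
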