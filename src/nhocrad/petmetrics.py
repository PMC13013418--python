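"""NHOC and conventional PET metrics on a lesion mask.

The normalised hotspot-to-centroid distance (NHOC) is a dimensionless
measure of how peripheral a tumour's metabolic hotspot sits.  With
``x_sm`` the physical coordinates of the SUVmax voxel and ``x_c`` the
geometric centroid of the lesion mask,

    HOC  = ||x_sm - x_c||            (mm; minimum over tied SUVmax voxels)
    MV   = N * V_v                   (metabolic volume; N lesion voxels of V_v mm^3)
    MSR  = (3 MV / 4π)^(1/3)         (radius of the volume-equivalent sphere)
    NHOC = HOC / MSR

NHOC near 0 means the hotspot sits at the tumour's core; near 1, at its
surface — the configuration associated with clonal drift of aggressive
subpopulations towards the periphery and poorer prognosis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imgvol import BinaryMask, ScalarVolume, require_same_geometry, voxel_centres


@dataclass(frozen=True)
class NHOCResult:
    hotspot_xyz: tuple[float, float, float]
    centroid_xyz: tuple[float, float, float]
    hoc_mm: float
    n_voxels: int
    voxel_volume_mm3: float
    mv_mm3: float
    msr_mm: float
    nhoc: float
    n_hotspot_ties: int


@dataclass(frozen=True)
class ConventionalMetrics:
    suv_max: float
    suv_mean: float
    mtv_ml: float
    tlg: float


def compute_nhoc(
    pet: ScalarVolume, lesion: BinaryMask, suv_weighted_centroid: bool = False
) -> NHOCResult:
    """NHOC of a lesion.

    The centroid is the unweighted geometric centroid of the mask voxel
    centres; an SUV-weighted variant is available behind the flag for
    sensitivity analysis.  When several voxels tie at SUVmax, HOC is the
    minimum centre-to-centroid distance over the tied candidates and the
    tie count is reported.
    """
    require_same_geometry(pet, lesion)
    if lesion.n_voxels == 0:
        raise ValueError("lesion mask is empty")
    centres = voxel_centres(lesion)
    suv = pet.values[lesion.values]
    suv_max = float(suv.max())
    if suv_max <= 0:
        raise ValueError("SUVmax within the lesion is not positive")

    if suv_weighted_centroid:
        centroid = (centres * suv[:, None]).sum(axis=0) / suv.sum()
    else:
        centroid = centres.mean(axis=0)

    ties = centres[suv == suv_max]
    dists = np.linalg.norm(ties - centroid, axis=1)
    k = int(np.argmin(dists))
    hoc = float(dists[k])

    n = lesion.n_voxels
    vv = lesion.geometry.voxel_volume_mm3
    mv = n * vv
    msr = (3.0 * mv / (4.0 * np.pi)) ** (1.0 / 3.0)
    return NHOCResult(
        hotspot_xyz=tuple(float(x) for x in ties[k]),
        centroid_xyz=tuple(float(x) for x in centroid),
        hoc_mm=hoc,
        n_voxels=n,
        voxel_volume_mm3=vv,
        mv_mm3=mv,
        msr_mm=msr,
        nhoc=hoc / msr,
        n_hotspot_ties=int(len(ties)),
    )


def compute_conventional(pet: ScalarVolume, lesion: BinaryMask) -> ConventionalMetrics:
    """SUVmax, SUVmean, MTV (ml) and TLG = SUVmean × MTV over the lesion."""
    require_same_geometry(pet, lesion)
    if lesion.n_voxels == 0:
        raise ValueError("lesion mask is empty")
    suv = pet.values[lesion.values]
    mtv_ml = lesion.n_voxels * lesion.geometry.voxel_volume_mm3 / 1000.0
    suv_mean = float(suv.mean())
    return ConventionalMetrics(
        suv_max=float(suv.max()),
        suv_mean=suv_mean,
        mtv_ml=mtv_ml,
        tlg=suv_mean * mtv_ml,
    )
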