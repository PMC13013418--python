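"""Multi-regional VOI construction on PET.

Three labels per case: the MTV40 lesion (voxels above 40% of the lesion's
SUVmax), peri-tumoural annular shells of 1 cm thickness grown outward from
the lesion boundary by a Euclidean distance transform in physical mm, and
2-cm-diameter background spheres placed in normal-appearing lung with their
centres 2 cm beyond the outer annulus edge.

Connectivity for connected components and zones is 26-neighbour in 3-D
throughout the package.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .imgvol import BinaryMask, ScalarVolume, VolumeGeometry, require_same_geometry, write_volume

logger = logging.getLogger(__name__)

# 26-connectivity structuring element, shared package-wide
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds and geometry of the three-label VOI system (defaults in mm/ml)."""

    threshold_fraction: float = 0.40
    shell_thickness_mm: float = 10.0
    n_shells: int = 1
    background_diameter_mm: float = 20.0
    background_gap_mm: float = 20.0
    min_lesion_volume_ml: float = 5.0

    def __post_init__(self):
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold_fraction must lie in (0, 1)")
        for name in ("shell_thickness_mm", "background_diameter_mm",
                     "background_gap_mm", "min_lesion_volume_ml"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_shells < 1:
            raise ValueError("n_shells must be >= 1")


@dataclass
class VOISet:
    """Lesion + ordered annuli (shell 1 innermost) + background spheres.

    All masks share one geometry and are pairwise disjoint.
    """

    lesion: BinaryMask
    annuli: list[BinaryMask] = field(default_factory=list)
    background: list[BinaryMask] = field(default_factory=list)

    @property
    def geometry(self) -> VolumeGeometry:
        return self.lesion.geometry

    def all_masks(self) -> list[BinaryMask]:
        return [self.lesion, *self.annuli, *self.background]

    def validate_disjoint(self) -> None:
        masks = self.all_masks()
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                if np.any(masks[i].values & masks[j].values):
                    raise ValueError(
                        f"VOIs {masks[i].label!r} and {masks[j].label!r} overlap"
                    )

    def write(self, out_dir: str | Path, params: SegmentationParams | None = None) -> None:
        """One NIfTI per label plus a JSON sidecar with params and label names."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        labels = []
        for m in self.all_masks():
            write_volume(m, out_dir / f"{m.label}.nii.gz")
            labels.append(m.label)
        sidecar = {"labels": labels}
        if params is not None:
            sidecar["params"] = asdict(params)
        (out_dir / "voiset.json").write_text(json.dumps(sidecar, indent=2))


def _distance_to_mask_mm(mask: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    """Exact Euclidean distance (mm) from each voxel centre to the nearest set voxel."""
    return ndimage.distance_transform_edt(~mask, sampling=spacing)


def segment_mtv40(
    pet: ScalarVolume,
    seed: Sequence[int] | BinaryMask,
    params: SegmentationParams = SegmentationParams(),
) -> BinaryMask:
    """Semi-automated lesion segmentation at 40% of the lesion SUVmax.

    The threshold reference is the SUVmax of the seed's connected hot
    region (not the global image maximum), so nearby avid structures such
    as mediastinal nodes do not inflate the threshold.  The returned mask
    is the 26-connected component of the thresholded image containing the
    region's hottest voxel.

    Raises if the lesion volume falls below ``min_lesion_volume_ml``
    (default 5 ml): small lesions are excluded as unreliable to segment.
    """
    if isinstance(seed, BinaryMask):
        require_same_geometry(pet, seed)
        seed_idx = np.argwhere(seed.values)
        if seed_idx.size == 0:
            raise ValueError("seed mask is empty")
    else:
        seed_idx = np.asarray([seed], dtype=int)
        if np.any(seed_idx < 0) or np.any(seed_idx[0] >= np.asarray(pet.geometry.shape)):
            raise ValueError(f"seed {tuple(seed)} outside PET grid {pet.geometry.shape}")

    vals = pet.values
    noise_floor = float(np.percentile(vals, 50))
    seed_suv = float(max(vals[tuple(i)] for i in seed_idx))
    if seed_suv <= noise_floor:
        raise ValueError(
            f"seed SUV {seed_suv:.2f} at or below background level "
            f"{noise_floor:.2f}: seed appears to lie outside an avid lesion"
        )

    # grow the seed's connected hot region (above background) to find its SUVmax
    hot = vals > noise_floor
    lab, _ = ndimage.label(hot, structure=STRUCT_26)
    region_label = int(max(lab[tuple(i)] for i in seed_idx))
    region = lab == region_label
    suv_max = float(vals[region].max())

    thresholded = vals >= params.threshold_fraction * suv_max
    lab2, _ = ndimage.label(thresholded, structure=STRUCT_26)
    hottest = np.argwhere(region & (vals == suv_max))[0]
    lesion = lab2 == lab2[tuple(hottest)]

    mask = BinaryMask(geometry=pet.geometry, values=lesion, label="lesion")
    if mask.volume_ml < params.min_lesion_volume_ml:
        raise ValueError(
            f"lesion volume {mask.volume_ml:.2f} ml below the "
            f"{params.min_lesion_volume_ml} ml minimum-volume criterion"
        )
    logger.info("MTV40 lesion: %d voxels, %.2f ml", mask.n_voxels, mask.volume_ml)
    return mask


def build_annuli(
    lesion: BinaryMask,
    params: SegmentationParams = SegmentationParams(),
    body_mask: BinaryMask | None = None,
) -> list[BinaryMask]:
    """Consecutive annular shells grown outward from the lesion boundary.

    Shell k contains voxels whose centre-to-lesion Euclidean distance d (in
    physical mm, respecting anisotropic spacing) satisfies
    ``(k-1)·t < d <= k·t``.  Voxels outside ``body_mask`` (e.g. outside the
    lungs) are removed when a body mask is supplied.
    """
    if lesion.n_voxels == 0:
        raise ValueError("cannot build annuli around an empty lesion")
    t = params.shell_thickness_mm
    dist = _distance_to_mask_mm(lesion.values, lesion.geometry.spacing)
    shells = []
    for k in range(1, params.n_shells + 1):
        shell = (dist > (k - 1) * t) & (dist <= k * t)
        if body_mask is not None:
            require_same_geometry(lesion, body_mask)
            shell &= body_mask.values
        if not shell.any():
            logger.warning("annulus %d entirely clipped away", k)
        shells.append(
            BinaryMask(geometry=lesion.geometry, values=shell, label=f"annulus{k}")
        )
    return shells


def _sphere_mask(geom: VolumeGeometry, centre_mm: Sequence[float], radius_mm: float) -> np.ndarray:
    idx = np.indices(geom.shape)
    spacing = np.asarray(geom.spacing)
    origin = np.asarray(geom.origin)
    d2 = np.zeros(geom.shape)
    for ax in range(3):
        d2 += (origin[ax] + idx[ax] * spacing[ax] - centre_mm[ax]) ** 2
    return d2 <= radius_mm**2


def place_background_spheres(
    lesion: BinaryMask,
    annuli: Sequence[BinaryMask],
    centres: Sequence[Sequence[float]] | str = "auto",
    params: SegmentationParams = SegmentationParams(),
    lung_mask: BinaryMask | None = None,
) -> list[BinaryMask]:
    """Background lung-parenchyma spheres (default 2 cm diameter).

    With ``centres="auto"`` a single centre is placed on the ray from the
    lesion centroid through the outer annulus boundary, at
    ``background_gap_mm`` beyond the outer annulus edge, along the grid
    direction of largest clearance.  Manual mm centres are also accepted.
    Spheres must be disjoint from lesion and annuli.
    """
    if not annuli:
        raise ValueError("annuli must be built before background spheres")
    geom = lesion.geometry
    radius = params.background_diameter_mm / 2.0
    outer_mm = params.n_shells * params.shell_thickness_mm

    if isinstance(centres, str):
        if centres != "auto":
            raise ValueError(f"unknown centre mode {centres!r}")
        centroid = np.mean(
            np.argwhere(lesion.values) * np.asarray(geom.spacing)
            + np.asarray(geom.origin), axis=0,
        )
        dist = _distance_to_mask_mm(lesion.values, geom.spacing)
        target_d = outer_mm + params.background_gap_mm
        # deterministic direction: +x, then +y, +z, then negatives
        placed = None
        for direction in ((1, 0, 0), (0, 1, 0), (0, 0, 1),
                          (-1, 0, 0), (0, -1, 0), (0, 0, -1)):
            cand = centroid + np.asarray(direction, float) * (
                target_d + _max_lesion_halfwidth(lesion, direction)
            )
            idx = (cand - np.asarray(geom.origin)) / np.asarray(geom.spacing)
            pad = radius / np.asarray(geom.spacing)
            if np.all(idx - pad >= 0) and np.all(idx + pad <= np.asarray(geom.shape) - 1):
                iidx = tuple(np.round(idx).astype(int))
                if dist[iidx] >= target_d - max(geom.spacing):
                    placed = cand
                    break
        if placed is None:
            raise ValueError(
                "auto background-sphere centre falls outside the grid; "
                "supply a manual centre"
            )
        centres = [placed]

    spheres = []
    occupied = lesion.values.copy()
    for a in annuli:
        occupied |= a.values
    for i, c in enumerate(centres, start=1):
        vox = _sphere_mask(geom, c, radius)
        if lung_mask is not None:
            require_same_geometry(lesion, lung_mask)
            vox &= lung_mask.values
        if np.any(vox & occupied):
            raise ValueError(
                f"background sphere {i} at {tuple(float(x) for x in c)} "
                "overlaps the lesion or an annulus"
            )
        spheres.append(BinaryMask(geometry=geom, values=vox, label=f"background{i}"))
    return spheres


def _max_lesion_halfwidth(lesion: BinaryMask, direction: Sequence[float]) -> float:
    """Extent of the lesion from its centroid along an axis direction (mm)."""
    geom = lesion.geometry
    pts = np.argwhere(lesion.values) * np.asarray(geom.spacing) + np.asarray(geom.origin)
    centroid = pts.mean(axis=0)
    proj = (pts - centroid) @ np.asarray(direction, float)
    return float(proj.max())


def build_voiset(
    pet: ScalarVolume,
    seed: Sequence[int] | BinaryMask,
    params: SegmentationParams = SegmentationParams(),
    lung_mask: BinaryMask | None = None,
    background_centres: Sequence[Sequence[float]] | str = "auto",
) -> VOISet:
    """Full three-label construction: MTV40 lesion → annuli → background spheres."""
    lesion = segment_mtv40(pet, seed, params)
    annuli = build_annuli(lesion, params, body_mask=lung_mask)
    background = place_background_spheres(
        lesion, annuli, centres=background_centres, params=params, lung_mask=lung_mask
    )
    vs = VOISet(lesion=lesion, annuli=annuli, background=background)
    vs.validate_disjoint()
    return vs
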