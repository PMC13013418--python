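"""Feature extraction orchestration across VOIs, modalities and transforms.

Feature names are deterministic:
``<modality>.<voi>.<transform>.<family>.<feature>`` — e.g.
``PET.annulus1.wavelet-HHL.glszm.size_variance``.  The manifest of names
actually produced, with per-feature provenance, is exported alongside the
values so the feature set is auditable and reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ..imgvol import BinaryMask, ScalarVolume, check_same_geometry, derived_volume, resample
from ..voi import VOISet
from .discretise import discretise_fixed_bin_count, discretise_fixed_bin_width
from .filters import DEFAULT_WAVELET, log_filter, wavelet_subbands
from .firstorder import firstorder_features
from .fractal import fractal_dimension
from .shape import shape_features
from .texture import glcm_features, glrlm_features, glszm_features, ngtdm_features

logger = logging.getLogger(__name__)

ALL_FAMILIES = ("firstorder", "shape", "glcm", "glrlm", "glszm", "ngtdm")
MIN_VOI_VOXELS = 8


@dataclass(frozen=True)
class FeatureSpec:
    """Configuration of the feature extraction pass."""

    families: tuple[str, ...] = ALL_FAMILIES
    wavelet: str | None = DEFAULT_WAVELET
    log_sigmas_mm: tuple[float, ...] = (1.5, 2.5, 3.5)
    n_bins: int = 64
    bin_width: float | None = None  # overrides n_bins when set
    resample_spacing: tuple[float, float, float] | None = (3.0, 3.0, 5.0)
    include_fractal: bool = True
    fractal_on_intensity: bool = False  # binarise at VOI mean SUV instead of the mask

    def __post_init__(self):
        if not self.families:
            raise ValueError("at least one feature family required")
        unknown = set(self.families) - set(ALL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown families {sorted(unknown)}")
        if self.n_bins < 2:
            raise ValueError("bin count must be >= 2")


@dataclass
class FeatureVector:
    patient_id: str
    values: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, dict] = field(default_factory=dict)

    def add(self, name: str, value: float, modality: str, voi: str,
            family: str, transform: str) -> None:
        if name in self.values:
            raise ValueError(f"duplicate feature name {name}")
        self.values[name] = float(value)
        self.provenance[name] = {
            "modality": modality, "voi": voi, "family": family, "transform": transform,
        }

    def write_manifest(self, path: str | Path, spec: FeatureSpec | None = None) -> None:
        payload = {"features": self.provenance}
        if spec is not None:
            payload["spec"] = asdict(spec)
        Path(path).write_text(json.dumps(payload, indent=2, default=str))


def _crop_to_bbox(vol_values: np.ndarray, mask_values: np.ndarray, pad: int = 2):
    idx = np.argwhere(mask_values)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, mask_values.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return vol_values[sl], mask_values[sl]


def _discretise(vals_in_mask: np.ndarray, spec: FeatureSpec):
    if spec.bin_width is not None:
        levels = discretise_fixed_bin_width(vals_in_mask, spec.bin_width)
    else:
        levels = discretise_fixed_bin_count(vals_in_mask, spec.n_bins)
    return levels, int(levels.max())


def _texture_and_firstorder(vec: FeatureVector, vol_crop, mask_crop, spec,
                            modality, voi_label, transform) -> None:
    vals = vol_crop[mask_crop]
    flat_levels, n_levels = _discretise(vals, spec)
    level_grid = np.zeros(mask_crop.shape, dtype=np.int64)
    level_grid[mask_crop] = flat_levels

    def emit(family, feats):
        for k, v in feats.items():
            vec.add(f"{modality}.{voi_label}.{transform}.{family}.{k}", v,
                    modality, voi_label, family, transform)

    if "firstorder" in spec.families:
        emit("firstorder", firstorder_features(vals, flat_levels))
    if "glcm" in spec.families:
        emit("glcm", glcm_features(level_grid, n_levels))
    if "glrlm" in spec.families:
        emit("glrlm", glrlm_features(level_grid, n_levels))
    if "glszm" in spec.families:
        emit("glszm", glszm_features(level_grid, n_levels))
    if "ngtdm" in spec.families:
        emit("ngtdm", ngtdm_features(level_grid, n_levels))


def extract_features(
    vol: ScalarVolume,
    voiset: VOISet,
    spec: FeatureSpec = FeatureSpec(),
    patient_id: str = "case",
) -> FeatureVector:
    """Extract all configured features for one modality over all VOIs.

    The volume and masks are resampled to ``spec.resample_spacing`` (default
    the 3×3×5 mm analysis grid) before extraction; intensities use linear,
    masks nearest-neighbour interpolation.  VOIs with fewer than 8 voxels
    after resampling yield missing (NaN) values, never silent zeros.
    """
    masks = voiset.all_masks()
    if spec.resample_spacing is not None:
        vol = resample(vol, spec.resample_spacing, "linear")
        masks = [resample(m, spec.resample_spacing, "nearest") for m in masks]
    for m in masks:
        if not check_same_geometry(vol, m):
            raise ValueError(f"VOI {m.label!r} does not share the volume grid")

    vec = FeatureVector(patient_id=patient_id)
    modality = vol.modality

    for m in masks:
        if m.n_voxels < MIN_VOI_VOXELS:
            logger.warning("VOI %r has %d voxels (< %d): features set to missing",
                           m.label, m.n_voxels, MIN_VOI_VOXELS)
            vec.add(f"{modality}.{m.label}.original.firstorder.mean", float("nan"),
                    modality, m.label, "firstorder", "original")
            continue

        vol_crop, mask_crop = _crop_to_bbox(vol.values, m.values)
        _texture_and_firstorder(vec, vol_crop, mask_crop, spec,
                                modality, m.label, "original")

        if "shape" in spec.families:
            feats = shape_features(BinaryMask(geometry=_crop_geom(vol, mask_crop),
                                              values=mask_crop, label=m.label))
            for k, v in feats.items():
                vec.add(f"{modality}.{m.label}.original.shape.{k}", v,
                        modality, m.label, "shape", "original")

        if spec.include_fractal:
            if spec.fractal_on_intensity:
                inside = vol_crop[mask_crop]
                binarised = mask_crop & (vol_crop >= inside.mean())
                est = fractal_dimension(binarised)
            else:
                est = fractal_dimension(mask_crop)
            vec.add(f"{modality}.{m.label}.original.fractal.fd", est.fd,
                    modality, m.label, "fractal", "original")
            vec.add(f"{modality}.{m.label}.original.fractal.r_squared", est.r_squared,
                    modality, m.label, "fractal", "original")

        # filtered variants: texture + first-order on transformed intensities
        crop_vol = derived_volume(_template(vol, vol_crop), vol_crop)
        if spec.wavelet is not None and all(n >= 2 for n in vol_crop.shape):
            for tag, sub in wavelet_subbands(crop_vol, spec.wavelet).items():
                _texture_and_firstorder(vec, sub.values, mask_crop, spec,
                                        modality, m.label, f"wavelet-{tag}")
        for sigma in spec.log_sigmas_mm:
            filtered = log_filter(crop_vol, sigma)
            _texture_and_firstorder(vec, filtered.values, mask_crop, spec,
                                    modality, m.label, f"log-{sigma:g}mm")
    return vec


def _crop_geom(vol: ScalarVolume, crop_values: np.ndarray):
    from ..imgvol import VolumeGeometry

    return VolumeGeometry(shape=crop_values.shape, spacing=vol.geometry.spacing)


def _template(vol: ScalarVolume, crop_values: np.ndarray) -> ScalarVolume:
    out = ScalarVolume.__new__(ScalarVolume)
    out.geometry = _crop_geom(vol, crop_values)
    out.values = np.asarray(crop_values, dtype=np.float64)
    out.modality = vol.modality
    return out


def feature_table(vectors: list[FeatureVector]):
    """Stack per-patient FeatureVectors into a patients × features DataFrame."""
    import pandas as pd

    rows = {v.patient_id: v.values for v in vectors}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("patient_id")
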