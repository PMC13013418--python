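"""Wavelet and Laplacian-of-Gaussian image filters for texture extraction.

The wavelet decomposition is a one-level undecimated (stationary) 3-D
separable transform, so every sub-band image keeps the grid of the input
and VOI masks apply unchanged.  Sub-bands are tagged by three letters, one
per axis in axis order (x, y, z): L = low-pass, H = high-pass; e.g. "HHL"
is high-pass along x and y, low-pass along z.  The default filter pair is
the orthogonal coif1 wavelet (perfect reconstruction), recorded in output
metadata.
"""

from __future__ import annotations

import logging

import numpy as np
import pywt
from scipy import ndimage

from ..imgvol import ScalarVolume, derived_volume

logger = logging.getLogger(__name__)

DEFAULT_WAVELET = "coif1"

SUBBAND_TAGS = ["LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH"]


def wavelet_subbands(
    vol: ScalarVolume, wavelet: str = DEFAULT_WAVELET
) -> dict[str, ScalarVolume]:
    """One-level stationary 3-D wavelet decomposition into 8 same-size sub-bands.

    Axes shorter than 2 voxels cannot be decomposed.  Odd axes are
    edge-padded to even length for the transform and cropped back.
    """
    shape = vol.values.shape
    if any(n < 2 for n in shape):
        raise ValueError(f"every axis must have length >= 2, got {shape}")
    pad = [(0, n % 2) for n in shape]
    data = np.pad(vol.values, pad, mode="edge")
    coeffs = pywt.swtn(data, wavelet, level=1)[0]
    out = {}
    for key, band in coeffs.items():
        # pywt keys use 'a' (approximation) / 'd' (detail) per axis
        tag = key.replace("a", "L").replace("d", "H")
        cropped = band[tuple(slice(0, n) for n in shape)]
        out[tag] = derived_volume(vol, cropped)
    return out


def inverse_wavelet(
    subbands: dict[str, ScalarVolume], wavelet: str = DEFAULT_WAVELET
) -> np.ndarray:
    """Reconstruct the original grid from the 8 sub-bands (even axes only)."""
    coeffs = {
        tag.replace("L", "a").replace("H", "d"): sv.values for tag, sv in subbands.items()
    }
    return pywt.iswtn([coeffs], wavelet)


def log_filter(vol: ScalarVolume, sigma_mm: float, scale_normalise: bool = True) -> ScalarVolume:
    """Laplacian-of-Gaussian response at scale ``sigma_mm``.

    σ is specified in physical mm and converted per axis by the voxel
    spacing, so the filter is isotropic in space on anisotropic grids.
    The response is scale-normalised (multiplied by σ²) so magnitudes are
    comparable across scales, as is usual for multi-scale blob filtering.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be positive")
    spacing = vol.geometry.spacing
    if sigma_mm < min(spacing) / 2:
        logger.warning(
            "LoG sigma %.2f mm is below half the smallest voxel spacing %.2f mm",
            sigma_mm, min(spacing),
        )
    sigma_vox = [sigma_mm / s for s in spacing]
    # second derivatives must be taken per unit mm, not per voxel, so each
    # axis term carries a 1/spacing² factor; truncate=8 keeps the kernel's
    # zero-mean property to ~1e-15 so constant regions map to zero response
    data = vol.values.astype(np.float64)
    resp = np.zeros_like(data)
    for ax in range(3):
        order = [0, 0, 0]
        order[ax] = 2
        resp += ndimage.gaussian_filter(
            data, sigma=sigma_vox, order=order, truncate=8.0
        ) / spacing[ax] ** 2
    if scale_normalise:
        resp = resp * sigma_mm**2
    return derived_volume(vol, resp)
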