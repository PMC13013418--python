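"""Grey-level discretisation of VOI intensities.

Fixed bin count (default 64 per VOI) maps the VOI's intensity range onto
1..n and is invariant under affine intensity rescaling, which suits
multi-scanner SUV/HU data; fixed bin width is provided for protocols that
prefer absolute intensity resolution.
"""

from __future__ import annotations

import numpy as np


def discretise_fixed_bin_count(values: np.ndarray, n_bins: int = 64) -> np.ndarray:
    """Map intensities onto integer levels 1..n_bins over the value range."""
    if n_bins < 2:
        raise ValueError("bin count must be >= 2")
    values = np.asarray(values, float)
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return np.ones(values.shape, dtype=np.int64)
    levels = np.floor((values - lo) / (hi - lo) * n_bins).astype(np.int64) + 1
    return np.clip(levels, 1, n_bins)


def discretise_fixed_bin_width(values: np.ndarray, width: float) -> np.ndarray:
    """Map intensities onto integer levels with a fixed bin width."""
    if width <= 0:
        raise ValueError("bin width must be positive")
    values = np.asarray(values, float)
    lo = float(values.min())
    return (np.floor(values / width) - np.floor(lo / width)).astype(np.int64) + 1
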