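"""First-order (intensity histogram) features of a VOI."""

from __future__ import annotations

import numpy as np
from scipy import stats


def firstorder_features(values: np.ndarray, levels: np.ndarray) -> dict[str, float]:
    """Intensity statistics over the VOI.

    ``values`` are raw intensities of the VOI voxels; ``levels`` their
    discretised grey levels (for entropy and uniformity, which are
    histogram features).
    """
    v = np.asarray(values, float).ravel()
    lv = np.asarray(levels).ravel()
    n = v.size
    p = np.bincount(lv)[1:].astype(float)
    p = p[p > 0] / n
    mean = float(v.mean())
    out = {
        "mean": mean,
        "median": float(np.median(v)),
        "minimum": float(v.min()),
        "maximum": float(v.max()),
        "range": float(v.max() - v.min()),
        "variance": float(v.var()),
        "std": float(v.std()),
        "skewness": float(stats.skew(v)) if v.std() > 0 else 0.0,
        "kurtosis": float(stats.kurtosis(v, fisher=False)) if v.std() > 0 else 0.0,
        "energy": float((v**2).sum()),
        "rms": float(np.sqrt((v**2).mean())),
        "mad": float(np.abs(v - mean).mean()),
        "iqr": float(np.percentile(v, 75) - np.percentile(v, 25)),
        "p10": float(np.percentile(v, 10)),
        "p90": float(np.percentile(v, 90)),
        "entropy": float(-(p * np.log2(p)).sum()),
        "uniformity": float((p**2).sum()),
    }
    return out
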