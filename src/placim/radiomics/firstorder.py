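"""First-order (histogram) intensity features over an ROI.

Statistics are population statistics over the raw intensities inside the
ROI; entropy and uniformity are computed on the discretized histogram
(same binning as the texture features). Degenerate conventions for a
constant ROI: entropy 0, uniformity 1, skewness 0, kurtosis 0.
"""

from __future__ import annotations

import numpy as np

from .discretize import discretize_values


def first_order_features(values: np.ndarray, n_bins: int = 32) -> dict[str, float]:
    """The 18 first-order features of a 1D array of ROI intensities."""
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    n = x.size
    mean = x.mean()
    var = x.var()          # population variance
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    dev = x - mean
    m2 = var
    if m2 > 0:
        skew = (dev**3).mean() / m2**1.5
        kurt = (dev**4).mean() / m2**2   # Pearson (non-excess) kurtosis
    else:
        skew = kurt = 0.0
    robust = x[(x >= p10) & (x <= p90)]
    rmad = np.abs(robust - robust.mean()).mean() if robust.size else 0.0
    levels = discretize_values(x, n_bins)
    p_hist = np.bincount(levels)[1:].astype(np.float64) / n
    p_nz = p_hist[p_hist > 0]
    return {
        "firstorder_energy": float((x**2).sum()),
        # unit pixel spacing: the pixel "volume" factor is 1
        "firstorder_total_energy": float((x**2).sum()),
        "firstorder_entropy": float(-(p_nz * np.log2(p_nz)).sum()),
        "firstorder_minimum": float(x.min()),
        "firstorder_percentile10": float(p10),
        "firstorder_percentile90": float(p90),
        "firstorder_maximum": float(x.max()),
        "firstorder_mean": float(mean),
        "firstorder_median": float(p50),
        "firstorder_interquartile_range": float(p75 - p25),
        "firstorder_range": float(x.max() - x.min()),
        "firstorder_mean_absolute_deviation": float(np.abs(dev).mean()),
        "firstorder_robust_mean_absolute_deviation": float(rmad),
        "firstorder_root_mean_squared": float(np.sqrt((x**2).mean())),
        "firstorder_skewness": float(skew),
        "firstorder_kurtosis": float(kurt),
        "firstorder_variance": float(var),
        "firstorder_uniformity": float((p_nz**2).sum()),
    }
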