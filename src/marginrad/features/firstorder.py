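"""First-order intensity statistics over the in-VOI voxel sample.

Sixteen statistics with the standard radiomics definitions. Moments use
the population (ddof=0) convention; Kurtosis is the raw fourth
standardized moment m4/m2^2 (not excess). Uniformity is computed on the
discretized gray-level histogram, everything else on the continuous
intensities. For a constant sample, Skewness and Kurtosis use the 0
sentinel (flagged) and Uniformity is 1.
"""

from __future__ import annotations

import numpy as np

__all__ = ["FIRSTORDER_NAMES", "first_order_features"]

FIRSTORDER_NAMES = (
    "Mean", "Median", "Minimum", "Maximum", "Range", "Variance", "Skewness",
    "Kurtosis", "Energy", "RootMeanSquared", "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation", "InterquartileRange", "10Percentile",
    "90Percentile", "Uniformity",
)


def first_order_features(values: np.ndarray, levels: np.ndarray | None = None):
    """Compute the first-order panel.

    Parameters
    ----------
    values : 1D array of in-VOI intensities (>= 1 voxel).
    levels : optional 1D array of discretized gray levels for the same
        voxels; required for Uniformity.

    Returns
    -------
    (features, flags)
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty intensity sample")
    flags: list[str] = []
    mean = float(x.mean())
    var = float(x.var())  # population variance
    centred = x - mean
    if var > 0:
        m2 = var
        skew = float(np.mean(centred**3)) / m2**1.5
        kurt = float(np.mean(centred**4)) / m2**2
    else:
        skew = 0.0
        kurt = 0.0
        flags += ["Skewness", "Kurtosis"]
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.mean(np.abs(robust - robust.mean()))) if robust.size else 0.0
    if levels is not None:
        lv = np.asarray(levels).ravel()
        counts = np.bincount(lv)[1:]  # drop the out-of-mask sentinel 0
        p = counts[counts > 0] / lv.size
        uniformity = float(np.sum(p**2))
    else:
        uniformity = np.nan
    feats = {
        "Mean": mean,
        "Median": float(np.median(x)),
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "Range": float(x.max() - x.min()),
        "Variance": var,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Energy": float(np.sum(x**2)),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(centred))),
        "RobustMeanAbsoluteDeviation": rmad,
        "InterquartileRange": float(p75 - p25),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Uniformity": uniformity,
    }
    return feats, flags
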