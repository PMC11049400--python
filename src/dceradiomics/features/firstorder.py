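"""The 18 first-order intensity features.

Energy, TotalEnergy and RootMeanSquared add the configured intensity
shift before squaring so negative CT/filter-response values do not cancel;
Entropy and Uniformity are computed on the fixed-bin-width histogram.
Skewness and Kurtosis use population moments, with Kurtosis reported
without the -3 (Fisher) correction; a zero-variance ROI yields 0 for both
and is flagged.
"""

from __future__ import annotations

import numpy as np

from .preprocessing import discretize

_EPS = np.spacing(1.0)

FIRSTORDER_NAMES = (
    "10Percentile", "90Percentile", "Energy", "Entropy", "InterquartileRange",
    "Kurtosis", "Maximum", "Mean", "MeanAbsoluteDeviation", "Median", "Minimum",
    "Range", "RobustMeanAbsoluteDeviation", "RootMeanSquared", "Skewness",
    "TotalEnergy", "Uniformity", "Variance",
)


def first_order_features(values, bin_width: float = 25.0, shift: float = 0.0,
                         voxel_volume: float = 1.0) -> tuple[dict[str, float], set[str]]:
    """Compute the 18 first-order features over the masked intensities.

    Returns ``(features, flags)`` where ``flags`` names degenerate entries
    (e.g. Skewness of a constant ROI).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    flags: set[str] = set()

    n = x.size
    mean = float(x.mean())
    p10, p25, p75, p90 = (float(np.percentile(x, q)) for q in (10, 25, 75, 90))
    shifted = x + shift
    energy = float(np.sum(shifted**2))

    levels = discretize(x, bin_width)
    p = np.bincount(levels)[1:].astype(float) / n
    p_nz = p[p > 0]

    robust = x[(x >= p10) & (x <= p90)]
    if robust.size == 0:  # cannot happen for n >= 1, but keep the guard
        robust = x

    m2 = float(np.mean((x - mean) ** 2))
    if m2 > 0:
        skew = float(np.mean((x - mean) ** 3)) / m2**1.5
        kurt = float(np.mean((x - mean) ** 4)) / m2**2
    else:
        skew, kurt = 0.0, 0.0
        flags.update({"Skewness", "Kurtosis"})

    feats = {
        "10Percentile": p10,
        "90Percentile": p90,
        "Energy": energy,
        "Entropy": float(-np.sum(p_nz * np.log2(p_nz + _EPS))),
        "InterquartileRange": p75 - p25,
        "Kurtosis": kurt,
        "Maximum": float(x.max()),
        "Mean": mean,
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "Median": float(np.median(x)),
        "Minimum": float(x.min()),
        "Range": float(x.max() - x.min()),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(robust - robust.mean()))),
        "RootMeanSquared": float(np.sqrt(energy / n)),
        "Skewness": skew,
        "TotalEnergy": voxel_volume * energy,
        "Uniformity": float(np.sum(p_nz**2)),
        "Variance": m2,
    }
    return feats, flags
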