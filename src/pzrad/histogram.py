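"""First-order intensity histogram features of a masked VOI."""

from __future__ import annotations

import numpy as np
from scipy import stats

HISTOGRAM_FEATURE_NAMES = (
    "kurtosis",
    "maximum",
    "mean",
    "median",
    "minimum",
    "p10",
    "p25",
    "p75",
    "p90",
    "skewness",
    "std",
)


def histogram_features(values: np.ndarray, prefix: str = "", excess_kurtosis: bool = True) -> dict[str, float]:
    """The 11 first-order statistics of the kept VOI intensities.

    Percentiles use linear interpolation; skewness and kurtosis are the
    population (biased) moment estimators, kurtosis excess (Fisher) by
    default. A constant input yields skewness 0 and kurtosis 0 (excess
    convention) rather than an undefined ratio.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 values")
    constant = v.max() == v.min()
    sd = 0.0 if constant else float(v.std(ddof=1))
    if constant:
        skew = 0.0
        kurt = 0.0 if excess_kurtosis else 3.0
    else:
        skew = float(stats.skew(v, bias=True))
        kurt = float(stats.kurtosis(v, fisher=excess_kurtosis, bias=True))
    p10, p25, p75, p90 = np.percentile(v, [10, 25, 75, 90])
    feats = {
        "kurtosis": kurt,
        "maximum": float(v.max()),
        "mean": float(v.mean()),
        "median": float(np.median(v)),
        "minimum": float(v.min()),
        "p10": float(p10),
        "p25": float(p25),
        "p75": float(p75),
        "p90": float(p90),
        "skewness": skew,
        "std": sd,
    }
    if prefix:
        feats = {f"{prefix}_{k}": val for k, val in feats.items()}
    return feats
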