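"""Voxelwise ADC mapping from multi-b diffusion-weighted series.

The apparent diffusion coefficient is the decay rate of the monoexponential
model ``S(b) = S0 * exp(-b * ADC)``. The b = 0 frame is excluded from the
fit to suppress perfusion (pseudo-diffusion) contamination, which inflates
the low-b signal above the monoexponential line; the fit uses the nonzero
b-values only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ImageVolume


@dataclass
class DwSeries:
    """A diffusion-weighted acquisition: one frame per b-value (s/mm^2)."""

    frames: list[ImageVolume]
    bvalues: list[float]

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.bvalues):
            raise ValueError("frames and bvalues differ in length")
        b = np.asarray(self.bvalues, dtype=float)
        if np.any(b < 0):
            raise ValueError("b-values must be nonnegative")
        if np.any(np.diff(b) <= 0):
            raise ValueError("b-values must be strictly increasing")
        if int((b > 0).sum()) < 2:
            raise ValueError("need at least 2 nonzero b-values")
        shape0 = self.frames[0].shape
        for f in self.frames[1:]:
            if f.shape != shape0:
                raise ValueError("DW frames do not share geometry")


def fit_adc_map(series: DwSeries, method: str = "loglinear") -> ImageVolume:
    """Fit the monoexponential decay voxelwise; returns an ADC volume in mm^2/s.

    ``loglinear`` (default) regresses ln S(b) on b by ordinary least squares
    over the nonzero b-values; ADC is minus the slope. ``nonlinear`` refines
    each voxel with a Levenberg-Marquardt fit of the exponential itself,
    seeded by the log-linear estimate. Voxels with any nonpositive intensity
    at a nonzero b cannot be log-fitted; their ADC is set to 0 and counted
    in the QC attribute ``n_nonpositive`` attached to the result.
    """
    b = np.asarray(series.bvalues, dtype=float)
    nz = b > 0
    bnz = b[nz]
    stack = np.stack([f.data for f, use in zip(series.frames, nz) if use], axis=-1)

    valid = np.all(stack > 0, axis=-1)
    n_nonpositive = int((~valid).sum())

    logs = np.zeros_like(stack)
    np.log(stack, out=logs, where=stack > 0)
    # OLS slope of log-signal on b, closed form, vectorized over voxels
    b_center = bnz - bnz.mean()
    denom = float((b_center**2).sum())
    slope = (logs * b_center).sum(axis=-1) / denom
    adc = np.where(valid, -slope, 0.0)

    if method == "nonlinear":
        from scipy.optimize import curve_fit

        def model(bv, s0, d):
            return s0 * np.exp(-bv * d)

        it = np.nditer(valid, flags=["multi_index"])
        for ok in it:
            if not ok:
                continue
            idx = it.multi_index
            y = stack[idx]
            p0 = (float(np.exp(logs[idx].mean() + slope[idx] * bnz.mean())), max(float(adc[idx]), 1e-6))
            try:
                popt, _ = curve_fit(model, bnz, y, p0=p0, maxfev=2000)
                adc[idx] = popt[1]
            except RuntimeError:
                pass  # keep the log-linear estimate
    elif method != "loglinear":
        raise ValueError(f"unknown ADC fit method: {method!r}")

    out = ImageVolume(data=adc, spacing=series.frames[0].spacing, modality="adc")
    out.n_nonpositive = n_nonpositive  # QC count, informal attribute
    return out
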