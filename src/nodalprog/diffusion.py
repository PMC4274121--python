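"""Apparent diffusion coefficient (ADC) mapping from two b-values.

With only b = 0 and one diffusion-weighted volume, the ADC is the
two-point log-ratio estimator adc = ln(S0/Sb)/b per voxel.  Voxels with
non-positive signal in either input are flagged invalid; negative ADC
(noise pushing Sb above S0) is clipped to 0 and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ADCMap:
    """Per-voxel ADC (mm^2/s) with validity flags."""

    adc: np.ndarray
    valid: np.ndarray
    clipped: np.ndarray


def compute_adc(s0_vol, sb_vol, b: float) -> ADCMap:
    """Two-point ADC map: adc = ln(s0/sb)/b, b in s/mm^2."""
    if b <= 0:
        raise ValueError("b must be positive")
    s0 = np.asarray(s0_vol, dtype=float)
    sb = np.asarray(sb_vol, dtype=float)
    if s0.shape != sb.shape:
        raise ValueError("volume shapes differ")
    valid = (s0 > 0) & (sb > 0)
    adc = np.zeros(s0.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        adc[valid] = np.log(s0[valid] / sb[valid]) / b
    clipped = valid & (adc < 0)
    adc[clipped] = 0.0
    adc[~valid] = np.nan
    return ADCMap(adc=adc, valid=valid, clipped=clipped)


def roi_adc(adcmap: ADCMap, roi, statistic: str = "mean") -> float:
    """ROI ADC in 1e-3 mm^2/s units (the reporting convention).

    Mean (default) or median over valid ROI voxels only.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != adcmap.adc.shape:
        raise ValueError("roi grid does not match map grid")
    if not roi.any():
        raise ValueError("empty roi")
    use = roi & adcmap.valid
    if not use.any():
        raise ValueError("roi contains no valid voxels")
    v = adcmap.adc[use]
    stat = np.mean(v) if statistic == "mean" else np.median(v)
    return float(stat * 1e3)
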