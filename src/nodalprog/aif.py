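"""Arterial input function (AIF) models.

The pharmacokinetic fitter needs the arterial plasma gadolinium
concentration Cp(t).  Patient-specific AIF extraction is out of scope;
instead we provide the standard population-average bolus shape (two
Gaussians for the first and second pass plus a sigmoid-modulated
exponential washout) fitted by Parker et al. to 3 T DCE data at the
standard 0.1 mmol/kg dose, scaled linearly with dose.  A measured curve
can be supplied instead via :meth:`AIF.from_samples`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Population parameters (standard-dose bolus; amplitudes in mmol*min and mM,
# times/widths in minutes, rates in 1/min).
_A = (0.809, 0.330)
_T = (0.17046, 0.365)
_SIGMA = (0.0563, 0.132)
_ALPHA = 1.050
_BETA = 0.1685
_S = 38.078
_TAU = 0.483

_REFERENCE_DOSE = 0.1  # mmol/kg


def population_cp(t_min: np.ndarray) -> np.ndarray:
    """Evaluate the population AIF (mM) at times in minutes post-injection.

    Returns 0 for t <= 0 (pre-injection).
    """
    t = np.asarray(t_min, dtype=float)
    cp = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    gauss = np.zeros_like(tp)
    for a, mu, sig in zip(_A, _T, _SIGMA):
        gauss += a / (sig * np.sqrt(2.0 * np.pi)) * np.exp(-((tp - mu) ** 2) / (2.0 * sig**2))
    washout = _ALPHA * np.exp(-_BETA * tp) / (1.0 + np.exp(-_S * (tp - _TAU)))
    cp[pos] = gauss + washout
    return cp


@dataclass
class AIF:
    """Arterial plasma concentration curve on the dynamic time grid.

    Attributes
    ----------
    times : ndarray
        Seconds relative to injection (non-decreasing; values <= 0 are
        pre-injection frames).
    cp : ndarray
        Plasma concentration in mM; 0 for times <= 0.
    """

    times: np.ndarray
    cp: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        if self.times.size == 0:
            raise ValueError("empty time grid")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")
        if self.times.shape != self.cp.shape:
            raise ValueError("times and cp must have the same shape")

    @classmethod
    def from_samples(cls, times: np.ndarray, cp: np.ndarray) -> "AIF":
        """Wrap a measured plasma curve sampled on the frame grid."""
        return cls(np.asarray(times, float), np.asarray(cp, float))


def parker_aif(times: np.ndarray, dose: float = _REFERENCE_DOSE) -> AIF:
    """Population AIF on a time grid in seconds from injection.

    Parameters
    ----------
    times : array-like
        Non-decreasing times in seconds; entries <= 0 map to Cp = 0.
    dose : float
        Contrast dose in mmol/kg; the curve scales linearly with
        dose relative to the standard 0.1 mmol/kg.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("empty time grid")
    cp = population_cp(t / 60.0) * (dose / _REFERENCE_DOSE)
    return AIF(times=t, cp=cp)
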