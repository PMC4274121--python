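"""DCE-MRI pharmacokinetic mapping.

Pipeline: variable-flip-angle (VFA) T1 mapping of the pre-contrast tissue,
conversion of the dynamic spoiled-gradient-echo (SPGR) signal to contrast
agent concentration, and voxel-wise fitting of the extended Tofts/Kety
model

    Ct(t) = vp * Cp(t) + Ktrans * int_0^t Cp(u) exp(-kep (t-u)) du,

with kep = Ktrans / ve, yielding Ktrans (volume transfer constant,
1/min), ve (extravascular extracellular volume fraction), vp (plasma
volume fraction) and kep maps.

Unit conventions: T1 and TR in milliseconds, relaxivity r1 in
(mM s)^-1, concentrations in mM, dynamic times in seconds relative to
injection, Ktrans/kep in 1/min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .aif import AIF
from .config import AcquisitionConfig

DEFAULT_R1 = 3.7  # gadolinium relaxivity at 3 T, (mM s)^-1

# Tofts fit bounds and multi-start grid; the ktrans starts bracket the
# clinically plausible decade and guard against the local minimum at ve -> 1.
TOFTS_BOUNDS = ([0.0, 1e-3, 0.0], [5.0, 1.0, 0.5])
KTRANS_STARTS = (0.05, 0.3, 1.0)
_VE_START = 0.2
_VP_START = 0.02
_MAX_ITER = 200
# Tight tolerances: at high kep the (ktrans, ve) valley is nearly flat and a
# looser objective tolerance stops the solver well short of the optimum.
_FTOL = 1e-12
# VFA voxels whose best SPGR fit leaves more than this fraction of the mean
# signal as residual are inconsistent with the signal model (e.g. identical
# signal at every flip) and flagged non-converged.
_VFA_MISFIT_FRAC = 0.10


def spgr_signal(c, t10, m0, flip, tr, r1=DEFAULT_R1):
    """Steady-state SPGR signal at concentration ``c``.

    S = m0 sin(a) (1 - E1) / (1 - E1 cos(a)),  E1 = exp(-TR / T1(c)),
    with 1/T1(c) = 1/t10 + r1 c (t10, TR in ms; r1 in (mM s)^-1).
    """
    c = np.asarray(c, dtype=float)
    t10 = np.asarray(t10, dtype=float)
    if np.any(t10 <= 0):
        raise ValueError("t10 must be positive")
    if tr <= 0:
        raise ValueError("tr must be positive")
    r1_s = 1000.0 / t10 + r1 * c  # longitudinal rate in 1/s
    e1 = np.exp(-(tr / 1000.0) * r1_s)
    a = np.deg2rad(flip)
    return m0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


@dataclass
class T1Map:
    """Per-voxel pre-contrast T1 (ms), equilibrium signal scale and residual."""

    t10: np.ndarray
    m0: np.ndarray
    fit_error: np.ndarray
    converged: np.ndarray


@dataclass
class ConcentrationSeries:
    """Per-voxel concentration time-courses (mM) on the dynamic grid.

    ``ct`` has shape ``spatial + (n_frames,)``; ``times`` are seconds
    relative to injection.  Pre-injection frames are identically 0 by
    construction (baseline-referenced).  ``n_clipped`` counts negative
    concentrations clipped to 0 per voxel; ``unresolvable`` flags frames
    whose signal exceeded the SPGR saturation ceiling.
    """

    ct: np.ndarray
    times: np.ndarray
    n_clipped: np.ndarray
    unresolvable: np.ndarray


@dataclass
class PKMap:
    """Voxel-wise extended Tofts parameter maps with fit diagnostics."""

    ktrans: np.ndarray
    ve: np.ndarray
    vp: np.ndarray
    kep: np.ndarray
    rss: np.ndarray
    converged: np.ndarray


def fit_t1_vfa(vfa_signals, acq: AcquisitionConfig, refine: bool = True) -> T1Map:
    """Estimate (t10, m0) per voxel from variable-flip-angle SPGR signals.

    ``vfa_signals`` has shape ``spatial + (n_flips,)`` matching
    ``acq.flip_baseline``.  The linearized DESPOT solve (S/sin a regressed
    on S/tan a, slope = E1) provides the estimate, optionally refined by
    nonlinear least squares on the SPGR equation.  Degenerate voxels
    (all-zero, inconsistent, E1 outside (0, 1)) are flagged non-converged.
    """
    sig = np.asarray(vfa_signals, dtype=float)
    flips = np.asarray(acq.flip_baseline, dtype=float)
    if flips.size < 2 or np.unique(flips).size < 2:
        raise ValueError("need at least 2 distinct flip angles")
    if sig.shape[-1] != flips.size:
        raise ValueError("last axis of vfa_signals must match flip_baseline")

    spatial = sig.shape[:-1]
    flat = sig.reshape(-1, flips.size)
    a = np.deg2rad(flips)
    n = flat.shape[0]

    t10 = np.full(n, np.nan)
    m0 = np.full(n, np.nan)
    err = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)

    with np.errstate(divide="ignore", invalid="ignore"):
        y = flat / np.sin(a)
        x = flat / np.tan(a)
    # per-voxel simple linear regression y = E1 * x + b
    xm = x.mean(axis=1, keepdims=True)
    ym = y.mean(axis=1, keepdims=True)
    sxx = ((x - xm) ** 2).sum(axis=1)
    sxy = ((x - xm) * (y - ym)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = sxy / sxx
    b = ym[:, 0] - e1 * xm[:, 0]

    valid = np.isfinite(e1) & (e1 > 0.0) & (e1 < 1.0) & (b > 0.0)
    t10[valid] = -acq.tr / np.log(e1[valid])
    m0[valid] = b[valid] / (1.0 - e1[valid])
    ok[valid] = True

    if refine:
        for i in np.nonzero(valid)[0]:
            s_i = flat[i]

            def resid(p):
                return spgr_signal(0.0, p[0], p[1], flips, acq.tr) - s_i

            try:
                res = least_squares(
                    resid, x0=[t10[i], m0[i]],
                    bounds=([1.0, 0.0], [2e4, np.inf]),
                    ftol=_FTOL, max_nfev=_MAX_ITER,
                )
                t10[i], m0[i] = res.x
                err[i] = np.sqrt(np.mean(res.fun**2))
                scale = np.mean(np.abs(s_i))
                if scale > 0 and err[i] > _VFA_MISFIT_FRAC * scale:
                    ok[i] = False
            except Exception:
                ok[i] = False
    if not refine:
        pred = spgr_signal(0.0, t10[valid, None], m0[valid, None], flips, acq.tr)
        err[valid] = np.sqrt(np.mean((pred - flat[valid]) ** 2, axis=1))

    return T1Map(
        t10=t10.reshape(spatial),
        m0=m0.reshape(spatial),
        fit_error=err.reshape(spatial),
        converged=ok.reshape(spatial),
    )


def signal_to_concentration(
    dyn, t1map: T1Map, acq: AcquisitionConfig, r1: float = DEFAULT_R1
) -> ConcentrationSeries:
    """Invert the dynamic SPGR signal to gadolinium concentration.

    The baseline signal is the mean of the first ``acq.n_baseline_dynamics``
    frames; the effective equilibrium scale is re-derived per voxel from
    that baseline and the T1 map, so any global scale (coil gain, m0)
    cancels.  Per frame the SPGR equation is inverted for T1(t) and
    c = (1/T1(t) - 1/t10) / r1.  Negative concentrations (noise below
    baseline) are clipped to 0 and counted; signals at or above the
    saturation ceiling m0 sin(a) are flagged unresolvable.
    """
    dyn = np.asarray(dyn, dtype=float)
    spatial = dyn.shape[:-1]
    if t1map.t10.shape != spatial:
        raise ValueError("t1map grid does not match dynamic grid")
    nb = acq.n_baseline_dynamics
    n_frames = dyn.shape[-1]
    times = (np.arange(n_frames) - nb) * acq.dt

    a = np.deg2rad(acq.flip_dynamic)
    tr_s = acq.tr / 1000.0
    t10 = t1map.t10[..., None]
    r10 = 1000.0 / t10
    e10 = np.exp(-tr_s * r10)

    s_base = dyn[..., :nb].mean(axis=-1, keepdims=True)
    # effective m0 sin(a) from the measured baseline at the voxel's T1
    m0s = s_base * (1.0 - e10 * np.cos(a)) / (1.0 - e10)

    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (m0s - dyn) / (m0s - dyn * np.cos(a))
    unresolvable = ~np.isfinite(e1) | (e1 <= 0.0)
    e1 = np.where(unresolvable, e10, e1)
    r1_t = -np.log(e1) / tr_s
    ct = (r1_t - r10) / r1

    ct[..., :nb] = 0.0  # baseline-referenced by construction
    unresolvable[..., :nb] = False
    neg = ct < 0
    n_clipped = neg.sum(axis=-1)
    ct = np.where(neg, 0.0, ct)
    ct = np.where(np.isfinite(ct), ct, 0.0)
    return ConcentrationSeries(ct=ct, times=times, n_clipped=n_clipped, unresolvable=unresolvable)


def _exp_conv(cp: np.ndarray, t_min: np.ndarray, kep: float) -> np.ndarray:
    """I(t_n) = int_{t_0}^{t_n} Cp(u) exp(-kep (t_n - u)) du, Cp piecewise linear.

    Exact per-interval recursion; times in minutes, kep in 1/min.
    """
    n = t_min.size
    out = np.zeros(n)
    dt = np.diff(t_min)
    if kep * np.max(dt, initial=0.0) < 1e-10:
        # kep ~ 0: plain running trapezoid
        seg = 0.5 * (cp[1:] + cp[:-1]) * dt
        out[1:] = np.cumsum(seg)
        return out
    e = np.exp(-kep * dt)
    a0 = cp[:-1]
    slope = np.where(dt > 0, np.diff(cp) / np.where(dt > 0, dt, 1.0), 0.0)
    seg = a0 * (1.0 - e) / kep + slope * (dt / kep - (1.0 - e) / kep**2)
    acc = 0.0
    for i in range(n - 1):
        acc = acc * e[i] + seg[i]
        out[i + 1] = acc
    return out


def extended_tofts_forward(ktrans, ve, vp, aif: AIF, times) -> np.ndarray:
    """Tissue concentration curve of the extended Tofts model (mM).

    ``times`` in seconds must match the AIF grid; ktrans in 1/min.
    """
    if ve <= 0:
        raise ValueError("ve must be positive")
    times = np.asarray(times, dtype=float)
    if times.shape != aif.times.shape or not np.allclose(times, aif.times):
        raise ValueError("times must match the AIF grid")
    t_min = times / 60.0
    kep = ktrans / ve
    return vp * aif.cp + ktrans * _exp_conv(aif.cp, t_min, kep)


def _fit_voxel(ct: np.ndarray, cp: np.ndarray, t_min: np.ndarray):
    """Bounded multi-start least squares for one voxel curve."""
    if np.max(np.abs(ct)) == 0.0:
        return (0.0, _VE_START, 0.0, 0.0, True)

    def resid(p):
        kt, ve, vp = p
        model = vp * cp + kt * _exp_conv(cp, t_min, kt / ve)
        return model - ct

    best = None
    for kt0 in KTRANS_STARTS:
        res = least_squares(
            resid, x0=[kt0, _VE_START, _VP_START],
            bounds=TOFTS_BOUNDS, ftol=_FTOL, xtol=_FTOL, gtol=_FTOL,
            max_nfev=_MAX_ITER,
        )
        rss = float(res.cost * 2.0)
        if best is None or rss < best[1]:
            best = (res, rss)
    res, rss = best
    kt, ve, vp = res.x
    converged = bool(res.status > 0) and res.nfev < _MAX_ITER
    return (kt, ve, vp, rss, converged)


def fit_extended_tofts(cs: ConcentrationSeries, aif: AIF, mask) -> PKMap:
    """Fit the extended Tofts model voxel-wise inside ``mask``.

    Bounded nonlinear least squares over (ktrans, ve, vp) with a
    multi-start grid of ktrans initial values; kep is derived as
    ktrans/ve, never fit independently.  Requires at least 10
    post-injection frames.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cs.ct.shape[:-1]:
        raise ValueError("mask grid does not match concentration grid")
    if not mask.any():
        raise ValueError("empty mask")
    if np.sum(cs.times > 0) < 10:
        raise ValueError("need at least 10 post-injection frames")
    if cs.times.shape != aif.times.shape or not np.allclose(cs.times, aif.times):
        raise ValueError("concentration and AIF grids differ")

    spatial = mask.shape
    ktrans = np.full(spatial, np.nan)
    ve = np.full(spatial, np.nan)
    vp = np.full(spatial, np.nan)
    rss = np.full(spatial, np.nan)
    converged = np.zeros(spatial, dtype=bool)

    t_min = cs.times / 60.0
    for idx in zip(*np.nonzero(mask)):
        kt, v_e, v_p, r, ok = _fit_voxel(cs.ct[idx], aif.cp, t_min)
        ktrans[idx], ve[idx], vp[idx], rss[idx], converged[idx] = kt, v_e, v_p, r, ok

    with np.errstate(divide="ignore", invalid="ignore"):
        kep = ktrans / ve
    return PKMap(ktrans=ktrans, ve=ve, vp=vp, kep=kep, rss=rss, converged=converged)


def roi_summary(values, roi, converged=None) -> dict:
    """Mean/median/count of a parameter map over an ROI.

    Statistics are computed over converged voxels only; the number of
    excluded (non-converged) voxels is reported separately.
    """
    values = np.asarray(values, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != values.shape:
        raise ValueError("roi grid does not match map grid")
    if not roi.any():
        raise ValueError("empty roi")
    if converged is None:
        use = roi & np.isfinite(values)
    else:
        use = roi & np.asarray(converged, dtype=bool)
    n_excluded = int(roi.sum() - use.sum())
    if not use.any():
        raise ValueError("roi contains no converged voxels")
    v = values[use]
    return {
        "mean": float(np.mean(v)),
        "median": float(np.median(v)),
        "n_voxels": int(v.size),
        "n_excluded": n_excluded,
    }
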