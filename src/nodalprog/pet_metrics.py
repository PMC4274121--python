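"""FDG-PET nodal metrics: SUVmax, MTV and TLG.

The metabolic tumor volume (MTV) is delineated inside a drawn boundary
mask by a fixed SUV threshold (default 2.5), with a *strict* inequality
SUV > threshold — many tools use >=, so the boundary semantics are part
of the contract here.  Total lesion glycolysis (TLG) is the product of
the mean SUV over the MTV voxels and the MTV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

F18_HALF_LIFE_MIN = 109.77


@dataclass
class NodalPETMetrics:
    """SUV/volume metrics for one nodal target boundary.

    mtv in cm^3; tlg in SUV*cm^3; suv_mean is NaN when the MTV set is
    empty (flagged by ``mtv_empty``).
    """

    suv_max: float
    suv_mean: float
    mtv: float
    tlg: float
    n_voxels: int
    mtv_empty: bool


def pet_nodal_metrics(
    suv_vol, boundary, threshold: float = 2.5, voxel_volume: float = 1.0
) -> NodalPETMetrics:
    """Compute SUVmax / MTV / TLG inside a boundary mask.

    MTV voxel set = {v in boundary : SUV(v) > threshold} (strict);
    suv_max is taken over the whole boundary; suv_mean, mtv and tlg over
    the MTV set.  Empty MTV set gives mtv = tlg = 0 and suv_mean = NaN.
    """
    suv = np.asarray(suv_vol, dtype=float)
    boundary = np.asarray(boundary, dtype=bool)
    if suv.shape != boundary.shape:
        raise ValueError("boundary grid does not match SUV grid")
    if not boundary.any():
        raise ValueError("empty boundary")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    inside = suv[boundary]
    mtv_set = boundary & (suv > threshold)
    n = int(mtv_set.sum())
    mtv = n * voxel_volume
    if n == 0:
        return NodalPETMetrics(
            suv_max=float(inside.max()), suv_mean=float("nan"),
            mtv=0.0, tlg=0.0, n_voxels=0, mtv_empty=True,
        )
    suv_mean = float(suv[mtv_set].mean())
    return NodalPETMetrics(
        suv_max=float(inside.max()),
        suv_mean=suv_mean,
        mtv=float(mtv),
        tlg=float(suv_mean * mtv),
        n_voxels=n,
        mtv_empty=False,
    )


def pet_metrics_per_component(
    suv_vol, boundary, threshold: float = 2.5, voxel_volume: float = 1.0
) -> list[NodalPETMetrics]:
    """Per-connected-component metrics when one boundary spans several nodes."""
    boundary = np.asarray(boundary, dtype=bool)
    labels, n_comp = ndimage.label(boundary)
    return [
        pet_nodal_metrics(suv_vol, labels == k, threshold, voxel_volume)
        for k in range(1, n_comp + 1)
    ]


def compute_suv(
    activity_conc,
    injected_dose: float,
    body_weight: float,
    decay_interval: float = 0.0,
    half_life: float = F18_HALF_LIFE_MIN,
) -> np.ndarray:
    """Body-weight SUV from an activity-concentration volume.

    SUV = activity (kBq/mL) * weight (kg) / dose decayed to scan time
    (MBq); with kBq/mL == MBq/L and kg ~ L of body water the units
    cancel to a dimensionless ratio.  ``decay_interval`` (minutes) decays
    the injected dose by 2^(-dt/half_life); 0 applies no correction.
    """
    if injected_dose <= 0 or body_weight <= 0:
        raise ValueError("dose and weight must be positive")
    act = np.asarray(activity_conc, dtype=float)
    dose_decayed = injected_dose * 2.0 ** (-decay_interval / half_life)
    return act * body_weight / dose_decayed
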