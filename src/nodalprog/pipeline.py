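"""End-to-end composition of the imaging and survival stages.

Per patient: DCE pharmacokinetic mapping -> ADC mapping -> PET nodal
metrics -> covariate assembly; then the cohort-level survival layer
(univariate screen, forward-selection Cox, prognostic score groups).
Patients whose imaging stages fail are excluded with recorded reasons
rather than aborting the cohort run (mirroring clinical exclusions for
unevaluable lesions or artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dce_pk, diffusion, pet_metrics, prognostics
from .aif import AIF, parker_aif
from .config import PipelineConfig

DEFAULT_SCREEN_VARIABLES = [
    "hb", "gtv", "ktrans", "vp", "ve", "kep", "adc", "suv", "mtv", "tlg",
]


@dataclass
class PatientInputs:
    """Per-patient imaging inputs plus clinical follow-up.

    Imaging arrays may be omitted (None) when a covariate is supplied
    directly in ``clinical``.
    """

    patient_id: str
    time_months: float
    event: int
    vfa: np.ndarray | None = None          # spatial + (n_flips,)
    dce: np.ndarray | None = None          # spatial + (n_dynamics,)
    dce_mask: np.ndarray | None = None
    b0: np.ndarray | None = None
    b800: np.ndarray | None = None
    dwi_mask: np.ndarray | None = None
    suv: np.ndarray | None = None
    pet_boundary: np.ndarray | None = None
    voxel_volume: float | None = None      # cm^3, for MTV
    clinical: dict = field(default_factory=dict)  # e.g. hb, gtv


def process_patient(p: PatientInputs, config: PipelineConfig,
                    aif: AIF | None = None) -> dict:
    """Run the imaging stages for one patient, returning covariates."""
    acq = config.acquisition
    cov = dict(p.clinical)
    if p.dce is not None:
        if aif is None:
            aif = parker_aif(acq.frame_times())
        t1map = dce_pk.fit_t1_vfa(p.vfa, acq)
        cs = dce_pk.signal_to_concentration(p.dce, t1map, acq, config.r1)
        pk = dce_pk.fit_extended_tofts(cs, aif, p.dce_mask)
        for name in ("ktrans", "ve", "vp", "kep"):
            summ = dce_pk.roi_summary(getattr(pk, name), p.dce_mask, pk.converged)
            cov[name] = summ["median"]
        cov["vp"] = cov["vp"] * 1e3  # reporting convention: Vp x 10^3
    if p.b0 is not None:
        adcmap = diffusion.compute_adc(p.b0, p.b800, acq.b_nonzero)
        cov["adc"] = diffusion.roi_adc(adcmap, p.dwi_mask)
    if p.suv is not None:
        vv = p.voxel_volume if p.voxel_volume is not None else acq.voxel_volume
        m = pet_metrics.pet_nodal_metrics(
            p.suv, p.pet_boundary, config.suv_threshold, vv)
        cov["suv"] = m.suv_max
        cov["mtv"] = m.mtv
        cov["tlg"] = m.tlg
    return cov


def run_pipeline(
    config: PipelineConfig,
    patients: list[PatientInputs] | None = None,
    cohort: pd.DataFrame | None = None,
    screen_variables: list[str] | None = None,
    aif: AIF | None = None,
) -> dict:
    """Full cohort analysis from imaging inputs or a precomputed cohort.

    With ``patients``, every imaging stage runs per patient and failures
    are collected as exclusions; with ``cohort``, imaging stages are
    bypassed and only the survival layer runs.
    """
    exclusions: dict[str, str] = {}
    if cohort is None:
        if not patients:
            raise ValueError("need patients or a cohort table")
        rows = []
        for p in patients:
            try:
                cov = process_patient(p, config, aif=aif)
                rows.append({"id": p.patient_id, "time_months": p.time_months,
                             "event": p.event, **cov})
            except Exception as exc:
                exclusions[p.patient_id] = str(exc)
        if not rows:
            raise ValueError("all patients excluded; nothing to analyse")
        cohort = pd.DataFrame(rows)

    variables = screen_variables or [
        v for v in DEFAULT_SCREEN_VARIABLES if v in cohort.columns
    ]
    screen = prognostics.univariate_screen(
        cohort, variables, horizon=config.horizon_months)
    significant = screen.loc[screen["p"] < 0.05, "variable"].tolist()
    cox = (prognostics.cox_fit(cohort, significant, selection="forward")
           if significant else None)

    report: dict = {
        "n_patients": int(len(cohort)),
        "n_events": int(cohort["event"].sum()),
        "exclusions": exclusions,
        "univariate": screen,
        "significant_univariate": significant,
        "cox": None if cox is None else {
            "selected": cox.selected,
            "summary": cox.summary,
            "path": cox.path,
            "excluded": cox.excluded,
        },
    }
    if {"hb", "ve", "adc"}.issubset(cohort.columns):
        report["score_groups"] = prognostics.score_group_analysis(
            cohort, config.score, horizon=config.horizon_months)
    return report
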