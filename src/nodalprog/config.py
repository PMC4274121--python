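"""Configuration objects shared across the pipeline.

Defaults mirror the acquisition protocol the pipeline was designed around:
a 3 T spoiled gradient-echo DCE series (TR/TE 3.5/1.13 ms, variable flip
angles 4/8/15/25 degrees for baseline T1 mapping, 15 degrees dynamic,
80 frames at 3.3 s), two-point DWI at b = 0/800 s/mm^2, and an SUV-2.5
threshold for PET metabolic tumor volume.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path


@dataclass
class AcquisitionConfig:
    """MR acquisition constants used by phantoms and fitters.

    Parameters
    ----------
    tr, te : float
        Repetition / echo time in milliseconds.
    flip_baseline : list of float
        Flip angles (degrees) of the pre-contrast variable-flip-angle scans.
    flip_dynamic : float
        Flip angle (degrees) of the dynamic series.
    n_dynamics : int
        Number of dynamic frames.
    dt : float
        Temporal resolution of the dynamic series in seconds.
    n_baseline_dynamics : int
        Pre-contrast frames at the head of the dynamic series; the contrast
        bolus is injected at the end of the last baseline frame.
    b_values : list of float
        Diffusion weightings in s/mm^2; must contain 0 and exactly one
        positive value.
    voxel_volume : float
        Voxel volume in cm^3.
    """

    tr: float = 3.5
    te: float = 1.13
    flip_baseline: list[float] = field(default_factory=lambda: [4.0, 8.0, 15.0, 25.0])
    flip_dynamic: float = 15.0
    n_dynamics: int = 80
    dt: float = 3.3
    n_baseline_dynamics: int = 4
    b_values: list[float] = field(default_factory=lambda: [0.0, 800.0])
    voxel_volume: float = 4.05e-3

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (self.n_dynamics >= self.n_baseline_dynamics >= 1):
            raise ValueError("need n_dynamics >= n_baseline_dynamics >= 1")
        for f in list(self.flip_baseline) + [self.flip_dynamic]:
            if not (0.0 < f <= 90.0):
                raise ValueError(f"flip angle {f} outside (0, 90] degrees")
        b = sorted(self.b_values)
        if len(b) != 2 or b[0] != 0.0 or b[1] <= 0.0:
            raise ValueError("b_values must contain 0 and exactly one positive value")

    @property
    def b_nonzero(self) -> float:
        return max(self.b_values)

    def frame_times(self) -> "np.ndarray":
        """Frame times in seconds relative to injection.

        Injection happens at the end of the baseline frames, so the first
        ``n_baseline_dynamics`` frames have negative times.
        """
        import numpy as np

        idx = np.arange(self.n_dynamics)
        return (idx - self.n_baseline_dynamics) * self.dt


@dataclass
class ScoreConfig:
    """Cutoffs and orientation of the 3-factor prognostic score.

    The score adds one point per adverse factor: low hemoglobin, low Ve
    (extravascular extracellular volume fraction) and high ADC.  The risk
    side of each cutoff is closed (<= for hb and ve, >= for adc).
    """

    hb_cutoff: float = 14.3       # g/dL; risk if hb <= cutoff
    ve_cutoff: float = 0.23       # dimensionless; risk if ve <= cutoff
    adc_cutoff: float = 1.14      # x 1e-3 mm^2/s; risk if adc >= cutoff
    high_risk_min_score: int = 2  # group "high" iff score >= this


@dataclass
class PipelineConfig:
    """Bundle of all stage configuration, JSON round-trippable."""

    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    r1: float = 3.7               # Gd relaxivity at 3 T, (mM s)^-1
    suv_threshold: float = 2.5    # MTV delineation threshold
    score: ScoreConfig = field(default_factory=ScoreConfig)
    horizon_months: float = 36.0  # 3-year outcome horizon
    seed: int = 0
    out_dir: str = "."

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "acquisition" in d and isinstance(d["acquisition"], dict):
            d["acquisition"] = AcquisitionConfig(**d["acquisition"])
        if "score" in d and isinstance(d["score"], dict):
            d["score"] = ScoreConfig(**d["score"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
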