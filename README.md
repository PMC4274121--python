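# nodalprog

Pretreatment multimodality-imaging prognostics for neck (nodal) control
after chemoradiation in head-and-neck squamous cell carcinoma:
a tested, reusable implementation of the full analysis chain from raw
image physics to the survival statistics, exercised end-to-end on
synthetic phantoms and simulated cohorts with known ground truth.

It is aimed at quantitative-imaging and clinical-statistics researchers
who want each stage of such a pipeline as an auditable, recomposable
library function rather than a one-off analysis script.

## What it computes

**DCE-MRI pharmacokinetics** (`nodalprog.dce_pk`). Variable-flip-angle
T1 mapping from spoiled gradient-echo (SPGR) baselines (4°/8°/15°/25°,
TR 3.5 ms), inversion of the dynamic SPGR signal to gadolinium
concentration via 1/T1(c) = 1/T1₀ + r₁c, and voxel-wise fitting of the
extended Tofts/Kety model

    Ct(t) = vp·Cp(t) + Ktrans ∫₀ᵗ Cp(u)·e^(−kep(t−u)) du,   kep = Ktrans/ve,

giving Ktrans (volume transfer constant, min⁻¹), ve (extravascular
extracellular volume fraction), vp (plasma volume fraction) and kep
maps. Cp(t) is a Parker-style population arterial input function or a
measured curve.

**DWI** (`nodalprog.diffusion`). Two-point apparent diffusion
coefficient maps, ADC = ln(S₀/S_b)/b at b = 800 s/mm², and ROI values
in the usual ×10⁻³ mm²/s convention.

**FDG-PET nodal metrics** (`nodalprog.pet_metrics`). SUVmax over a
drawn boundary, metabolic tumor volume by the fixed threshold SUV > 2.5
(strict inequality), and total lesion glycolysis TLG = SUVmean × MTV.

**Survival layer** (`nodalprog.prognostics`). Kaplan–Meier estimation,
log-rank tests, log-rank-optimal cutoff dichotomisation, a univariate
screen of 3-year control rates, Cox proportional-hazards regression
with Efron tie handling and score-test forward selection, Spearman
correlations, and the additive 3-factor prognostic score
(1 point each for hemoglobin ≤ 14.3 g/dL, ve ≤ 0.23,
ADC ≥ 1.14×10⁻³ mm²/s; scores 2–3 define the high-risk group).

**Phantoms** (`nodalprog.phantoms`). Forward simulators for everything
above — SPGR dynamic series from known Tofts parameters, diffusion
decay pairs, PET lesions, and Weibull proportional-hazards cohorts —
so every estimator has a parameter-recovery test surface.

## Worked example

```python
import numpy as np
from nodalprog import dce_pk, phantoms
from nodalprog.aif import parker_aif
from nodalprog.config import AcquisitionConfig
from nodalprog.prognostics import prognostic_score

acq = AcquisitionConfig()               # TR 3.5 ms, 80 frames at 3.3 s, ...
aif = parker_aif(acq.frame_times())     # population Cp(t) on the frame grid

truth = phantoms.TissueTruth(           # one voxel with known parameters
    ktrans=np.array([0.49]), ve=np.array([0.18]), vp=np.array([0.0024]),
    t10=np.array([1000.0]), adc=np.array([0.95e-3]))
dyn = phantoms.gen_dce_series(truth, aif, acq, noise_sd=0.0)
vfa = np.stack([dce_pk.spgr_signal(0.0, truth.t10, 1000.0, f, acq.tr)
                for f in acq.flip_baseline], axis=-1)

t1map = dce_pk.fit_t1_vfa(vfa, acq)
cs = dce_pk.signal_to_concentration(dyn, t1map, acq)
pk = dce_pk.fit_extended_tofts(cs, aif, np.ones(1, bool))
print(f"Ktrans {pk.ktrans[0]:.3f}  ve {pk.ve[0]:.3f}  vp {pk.vp[0]:.4f}")

print(prognostic_score(hb=15.9, ve=0.34, adc=0.78))
print(prognostic_score(hb=12.7, ve=0.07, adc=1.24))
```

Output:

```
Ktrans 0.490  ve 0.180  vp 0.0024
{'score': 0, 'group': 'low'}
{'score': 3, 'group': 'high'}
```

The fitted voxel recovers its generating parameters exactly (noiseless
round trip), and the two patients illustrate the score: the first has
no adverse factor (high hemoglobin, high ve, low ADC — low risk), the
second has all three (score 3, high risk).

A command-line surface wraps the same functions:

```sh
nodalprog simulate cohort --seed 1 --out sim/
nodalprog survival --cohort sim/cohort.tsv --out report/
nodalprog score --cohort sim/cohort.tsv --out report/
```

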