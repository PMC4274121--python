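# Methods

This note documents the models, numerical choices and limitations of
`nodalprog`, stage by stage.

## Signal model and T1 mapping

Dynamic and baseline images follow the steady-state spoiled
gradient-echo (SPGR) equation

    S = M0 · sin α · (1 − E1) / (1 − E1 cos α),   E1 = exp(−TR/T1),

with TR = 3.5 ms and dynamic flip α = 15° by default. Contrast agent
shortens T1 through the fast-exchange linear model
1/T1(c) = 1/T1₀ + r₁·c with gadolinium relaxivity r₁ = 3.7 (mM·s)⁻¹ at
3 T (configurable; a literature-standard value, required to close the
signal model because relaxivity is a property of the agent/field, not
of the acquisition).

Pre-contrast T1₀ and M0 come from variable-flip-angle baselines
(4°, 8°, 15°, 25°) via the linearized DESPOT regression of S/sin α on
S/tan α (slope = E1), refined per voxel by bounded nonlinear least
squares on the SPGR equation. Voxels are flagged non-converged — never
silently zeroed — when the linear solve leaves E1 outside (0, 1)
(e.g. all-zero data) or when the refined fit's RMS residual exceeds 10%
of the mean signal, which catches data inconsistent with the model such
as identical signal at every flip.

## Signal → concentration

The baseline signal is the mean of the first 4 dynamic frames (the
pre-injection frames; the bolus is injected at the end of frame 4, so
frame times are (i − 4)·3.3 s). The effective M0·sin α is re-derived per
voxel from that baseline and the T1 map, so any global scale factor
(coil gain, generator M0) cancels exactly. Each frame is then inverted
algebraically for E1 and hence T1(t), and c = (1/T1(t) − 1/T1₀)/r₁.
Pre-injection frames are set to 0 by construction. Negative
concentrations (noise below baseline) are clipped to 0 with a per-voxel
clip counter; signals at or above the saturation ceiling M0·sin α are
flagged unresolvable for that frame (the concentration there is left at
0 rather than extrapolated).

## Arterial input function

Patient-specific AIF measurement is out of scope; the package uses the
standard population bolus shape (two Gaussians for first and second
pass plus a sigmoid-modulated exponential washout) at the standard
0.1 mmol/kg dose, scaling linearly with dose, evaluated on the frame
grid and zero at non-positive times. A measured curve can be supplied
through `AIF.from_samples`, so the population choice is a default, not
baked in. No bolus-arrival-time parameter is fitted: tissue and plasma
curves share the frame grid.

## Extended Tofts model and fitting

The tissue curve is Ct(t) = vp·Cp(t) + Ktrans·(Cp ⊛ e^(−kep·t)) with
kep = Ktrans/ve. The convolution is evaluated by the exact per-interval
recursion for piecewise-linear Cp (analytic integral of a linear
segment against the exponential kernel), which is numerically stable
for arbitrary kep and reduces to a running trapezoid as kep → 0.
Because Cp itself is sampled at the 3.3 s frame spacing, the few frames
during first-pass bolus transit differ from a 10× refined reference by
up to a few percent of the peak; from ~20 s post-injection onward the
discrete convolution agrees with the refined one to better than 0.5%.

Voxel-wise fitting is bounded nonlinear least squares over
(Ktrans, ve, vp) with bounds [0, 5] min⁻¹, (10⁻³, 1], [0, 0.5] and a
multi-start grid Ktrans ∈ {0.05, 0.3, 1.0} min⁻¹ (ve 0.2, vp 0.02
starts), keeping the lowest-RSS solution; the multi-start guards
against the known local minimum at ve → 1. kep is derived as
Ktrans/ve, never fit independently. Solver tolerances are 10⁻¹² on
objective, step and gradient: at high kep (fast washout, e.g. ve ≈ 0.01
with large Ktrans) the model degenerates toward Ct ≈ (vp + ve)·Cp and
the (Ktrans, ve) valley is nearly flat, so looser tolerances stop the
solver visibly short of the optimum. Voxels are flagged non-converged
after 200 function evaluations. An all-zero curve is a documented fast
path: converged, with Ktrans = vp = 0.

ROI exports report both mean and median over converged voxels; the
median is the default (robust to fit outliers at lesion margins).
Whether a clinical ROI value should be a mean or a median is a
reporting convention, not a property of the data — both are available.

## ADC

With exactly two b-values (0 and 800 s/mm²) the maximum-likelihood
noise-free estimator is the log-ratio adc = ln(S₀/S_b)/b per voxel;
no multi-b weighted fit applies. Voxels with non-positive signal are
flagged invalid; negative ADC (noise pushing S_b above S₀) is clipped
to 0 and flagged. ROI values are the mean over valid voxels (median
available), reported in ×10⁻³ mm²/s. Magnitude (Rician) noise biases
the two-point estimator; at ROI SNR ≥ 30 the bias of the ROI mean is
below 2% (verified by simulation in the test suite).

## PET metrics

MTV is delineated inside a drawn boundary mask as the set of voxels
with SUV strictly greater than the threshold (default 2.5). The strict
inequality is deliberate and tested — many tools use ≥, and the voxel
at exactly the threshold changes MTV. SUVmax is taken over the whole
boundary; SUVmean, MTV = n·voxel-volume and TLG = SUVmean·MTV over the
delineated set (TLG ≡ SUVmean·MTV is an exact identity of the output,
not an approximation). One boundary may span several nodes; metrics
are reported per boundary, with a per-connected-component option. SUV
is body-weight normalized, SUV = activity·weight/dose, with optional
¹⁸F decay correction of the injected dose (half-life 109.77 min). No
partial-volume correction is applied.

## Survival statistics

Kaplan–Meier and Cox fitting are performed through `lifelines`
(product-limit estimator; Efron tie handling, Newton optimization
tightened to 10⁻⁹ precision); log-rank through its chi-square
formulation with hypergeometric variance. Efron tie handling is the
default because month-resolution follow-up ties heavily. 3-year rates
are read from the Kaplan–Meier step function at exactly 36.0 months
(the estimate includes events occurring at the query time).

Optimal cutoffs scan midpoints between sorted distinct observed values,
constrained so each arm holds at least 10% of the cohort (preventing
degenerate arms), and return the split maximizing the log-rank
chi-square, breaking ties toward the more balanced split. **No
multiplicity correction is applied to the searched cutoff's p-value**;
the anti-conservatism this induces relative to a prespecified split is
demonstrated by simulation in the test suite and documented rather than
corrected, matching the descriptive univariate-table convention this
pipeline reproduces. The univariate screen dichotomises at a supplied
cutoff when one is given (log-rank p on that fixed split) and at the
optimal cutoff otherwise.

Forward selection for the Cox model adds, at each step, the candidate
with the smallest score-test p-value while p < 0.05, with no removal
step. The score test evaluates the Efron partial-likelihood gradient
and observed information of the augmented model at the current MLE with
the new coefficient at zero (U᾿I⁻¹U ~ χ²₁); candidates with singular
information (collinear or constant) never enter. Wald hazard ratios
with 95% CIs are reported for the selected model. Univariate screening
uses the log-rank test on dichotomised variables rather than logistic
regression on the 3-year outcome: the log-rank path uses the censoring
information and matches the reported per-arm rates; both views of the
same dichotomy are close for administratively complete 3-year follow-up.

## Prognostic score

One point per adverse factor — hemoglobin ≤ 14.3 g/dL, ve ≤ 0.23,
ADC ≥ 1.14×10⁻³ mm²/s — with the risk side of every cutoff closed, so
values exactly at a cutoff count as risk. Scores 2–3 define the
high-risk group. Missing components raise (no partial scores). An
optional post-treatment 0/1 factor (local failure) extends the score to
0–4 with the same ≥ 2 high-risk threshold. Group analysis reports
per-group Kaplan–Meier rates at the horizon, the log-rank test, and the
Cox hazard ratio of high vs low; degenerate groupings (everyone on one
side) yield a flagged report instead of an exception.

## Synthetic data: what it emulates and what it does not

The phantoms reproduce the *forward physics* each estimator inverts —
SPGR steady-state signal at the protocol constants (TR/TE 3.5/1.13 ms,
flips 4/8/15/25° + 15° dynamic, 80 frames at 3.3 s, injection after
frame 4), extended Tofts concentration dynamics under the population
AIF, mono-exponential diffusion decay at b = 800 s/mm², uniform-SUV
spherical lesions, and Weibull proportional-hazards event times with
uniform censoring over the 7–49 month follow-up window (a scalar
window w means Uniform(0, w); w = 0 disables censoring). Cohort
covariate distributions are clipped normals/lognormals whose medians
and ranges match the reference 69-patient cohort (hemoglobin median
14.0 g/dL, Ktrans 0.49 min⁻¹, ve 0.18, ADC 0.95×10⁻³ mm²/s, …), with
adverse log-hazard weight on low hemoglobin, low ve and high ADC and a
baseline scaled so 3-year control sits near 63%.

They do **not** emulate realistic anatomy, k-space acquisition, motion
or susceptibility artifacts, B1 inhomogeneity, partial-volume effects,
inter-modality misregistration, or patient-specific AIF variability.
Noise is additive Gaussian by default (configurable): at the SNRs
tested the Gaussian/Rician distinction is immaterial and Gaussian keeps
the estimators unbiased for recovery tests; the Rician-bias property of
the ADC estimator is tested separately. Passing recovery tests
therefore demonstrates correctness of the *inversion chain*, not
robustness to every real-world confound.

## Problem sizes and tolerances used in validation

Noiseless pharmacokinetic recovery is checked on a 4×4 grid spanning
Ktrans 0.03–1.62 min⁻¹ × ve 0.01–0.69 (errors < 2%; in practice
~10⁻⁶%); stochastic recovery at SNR 20 on 200 voxels (median Ktrans
error < 10%; in practice < 1%). The log-rank type-I error is estimated
over 2000 null cohorts of n = 69 (band 0.03–0.07). Hazard-ratio
recovery uses cohorts of n = 2000; the acceptance script averages the
log-HR over 10 replicate cohorts to keep the Monte-Carlo error of the
reported value small. These sizes make the whole validation run in a
couple of minutes on one CPU while leaving the statistical checks
well-powered.

## Known limitations

- The extended Tofts model assumes fast water exchange and a
  well-mixed plasma compartment; no 2CXM or exchange-limited variants.
- Ktrans and ve are weakly identifiable at very high kep with 3.3 s
  sampling (the model degenerates toward (vp+ve)·Cp); noiseless fits
  still recover truth, but noisy high-kep voxels will show inflated
  variance.
- Masks must share the image grid; no registration or resampling.
- The cutoff search's multiplicity inflation is reported, not
  corrected.
- Survival simulation uses proportional hazards by construction, so it
  cannot probe non-proportional effects.
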