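# Methods

## The stiffness model

The compressive modulus of a printed GelMA/HAMA construct after enzymatic
digestion is represented by a reduced second-degree polynomial in four design
factors:

| factor | symbol | units | range (coded −1 … +1) |
|---|---|---|---|
| GelMA concentration | A | % w/v | 2.5 – 7.5 |
| digestion time | B | h | 0 – 24 |
| hyaluronidase concentration | C | U/mL | 0 – 1000 |
| HAMA concentration | D | % w/v | 1.5 – 3.0 |

The term set is {A, B, C, D, AB, AC, AD, BD, CD, B², C²}; the BC interaction
and the A², D² quadratics are deliberately absent (the reduced model, not a
full quadratic — an optional full-quadratic term set exists for fitting but is
off by default). Models carry coefficients only for terms they contain;
nothing is silently zero-filled, so fits and evaluations match the reduced
form exactly.

**Coding.** Coded units rescale each factor so its low bound maps to −1 and
its high bound to +1. The conversion implemented in `rsm.to_coded` /
`rsm.to_actual` is the exact polynomial change of variables x = m + h·u
(m = center, h = half-range): quadratic coefficients scale by h², interactions
by hᵢhⱼ, linear terms pick up contributions from interactions and quadratics
evaluated at the center, and the coded intercept is the actual model at the
design center. The round trip is exact to ~10⁻¹⁰ relative and evaluation is
form-invariant; both are property-tested. Coding is centered on the factorial
sweep bounds, not on any data centroid — recoding the published actual-units
equation over these bounds reproduces the published coded coefficients
(−32.44 for B, 39.73 for D, 13.11 for A×D, −18.91 for B×D, 23.95 for B²
exactly at two decimals), which is the evidence for that convention.

**The reference fixtures.** Both published equations ship as named fixtures:
`printed_actual_model()` and `printed_coded_model()`, coefficients exactly as
printed. The printed actual-units C² coefficient (0.0001) is a four-decimal
truncation; `refine_reference` repairs it from the coded value
(26.58 / 500² = 1.0632×10⁻⁴), and the refined model (`reference_model()`) is
the default for prediction and inverse design. Residual disagreements between
the recoded refined model and the printed coded equation (≈ 0.04 on the A and
A×C terms, ≈ 0.07 on the intercept and C) are fully explained by the
four-decimal/two-significant-figure truncation of the printed actual-units
coefficients — most visibly A×C, printed as −0.0099 where −12.33/1250 =
−0.009864.

## Fitting and diagnostics

Fits are ordinary least squares (via statsmodels) on a design matrix built in
coded units for conditioning (actual-units C² columns reach 10⁶); results are
converted to either form on request, and R², fitted values and ANOVA are
parameterization-invariant (tested). A rank-deficient matrix raises an error
naming the collinear columns; constant responses are rejected.

* **Adequate precision** uses the Design-Expert convention
  (max ŷ − min ŷ)/√(p·σ̂²/n) over the design points, p = number of parameters
  including the intercept. Whether n counts table rows or distinct design
  points is not standardized; both are exposed (`n_mode="rows"|"distinct"`),
  default rows. For replicated full-factorial data the two differ by
  √replicates. A perfect fit (σ̂ = 0) has infinite signal-to-noise; the
  standalone function raises, while fit diagnostics record +inf so degenerate
  noiseless pipelines still run.
* **ANOVA** is per-term partial (Type III); for single-df regression terms the
  partial F equals the squared t statistic. Significance flags use α = 0.05.
* **Prediction intervals** are for the mean of `n_new` future observations
  (default 1): ŷ ± t_{dof}·σ̂·√(1/n_new + x₀ᵀ(XᵀX)⁻¹x₀). The verification
  protocol compares the mean of triplicate simulated trials against the
  n_new = 3 interval, matching how verification experiments are averaged.

## Inverse design

`design_for_target` minimizes |ŷ(x) − target| over the design box with
L-BFGS-B (analytic gradient of the quadratic) from a fixed 3⁴ = 81-point
multistart — for a quadratic over a box this reliably finds the global
optimum, verified in tests against an exact face-enumeration oracle and a 21⁴
dense grid. Candidates within 10⁻⁶ kPa of the best residual are tied; ties
break toward minimal enzyme concentration, then minimal digestion time,
because harsh digestion is hostile to embedded cells. Infeasible targets
return an explicit result carrying the nearest achievable modulus (from the
multistart box extrema), never a silent clamp. Tissue presets (brain 1–4,
liver 1–10, lung 10–15, heart 30–60 kPa) target the range midpoint.
Predictions below 0 kPa are reported as-is with a physicality warning: the
quadratic is an empirical surrogate, not a physical law, and it extrapolates
negative in the hardest-digestion / softest-formulation corner of the box
(box minimum ≈ −28.9 kPa).

## Photopolymerization

The Jacobs working curve C_d = D_p ln(E/E_c) is fitted by OLS of cure depth
against ln(exposure); with exactly two points it passes through both. The
projector irradiance is often unknown, in which case exposure is time in
seconds and E_c is a critical *time* — the model is shift-invariant in
ln-space, so D_p is unaffected and E_c(dosage) = I·t_c when the irradiance I
is later known (tested as an algebraic identity). Negative predicted depths
mean no gelation; the library keeps the signed value (diagnostic), the CLI
reports 0 with a flag. Radial resolution follows
p = D·tan(π/n) − h/cos(π/n); p ≤ 0 flags merged lines, and the inversion for
the implied line width round-trips to 10⁻¹².

## Effective diffusivity

Axial fluorescence profiles are normalized affinely so the opening-side
intensity is 1 and the far end 0, which pins the proportionality constant of
the semi-infinite-medium solution F = erfc(x/(2√(D_eff·t))) to one; D_eff is
then the single free parameter of a nonlinear least-squares fit, run in
log₁₀(D) with bounds [−12, −2] and started from the value implied by the
half-maximum position (erfc(u) = ½ at u ≈ 0.4769). An amplitude-free
two-parameter mode exists for un-normalized data. Asymptotic standard errors
come from the Jacobian at the optimum via the delta method. The semi-infinite
constant-source assumption is taken as given; finite-length corrections and
digestion-coupled (time-varying) diffusivity are out of scope. On the
0–0.2 cm / 50-point imaging grid at t = 60 s, the diffusion front of the
intact gel spans only the first couple of grid points, so single noisy
profiles are high-variance estimators; recovery criteria are therefore stated
on medians over replicate profiles (noiseless recovery is exact to < 10⁻⁶
relative across D ∈ [10⁻⁹, 10⁻⁵] cm²/s).

## Synthetic data

The generators emulate the study conditions: the full factorial sweep
GelMA {2.5, 5.0, 7.5} × HAMA {1.5, 3.0} × Hase {0, 75, 150, 300, 500, 1000}
× time {0, 1, 2, 4, 8, 12, 24} in triplicate (756 rows), homoscedastic
Gaussian noise with SD 8 kPa on moduli, 20 µm on cure depths and 0.02 on
normalized intensities — scales chosen once to match reported measurement
SDs. An optional proportional-noise mode (CV-based) reflects the mild
heteroscedasticity visible in reported SDs but is off by default since no
error model is published. All generators are pure functions of
(parameters, seed); one integer seed drives a counter-based Philox generator
with an independent sub-stream per generator family.

Modulus draws below 0 kPa are truncated to the physical floor (count
reported) rather than resampled, keeping generators pure. Consequence worth
knowing: the reference quadratic is negative over part of the sweep grid, so
roughly 10 % of generated rows are censored at 0 and a fit to generated data
does not reproduce the generating coefficients exactly even without noise.
Fit-quality checks (R² ≥ 0.9, adequate precision > 4, 95 % PI coverage in
[0.93, 0.97]) hold under the full study conditions regardless; estimator
*calibration* tests (exact noiseless recovery, coefficient bias < 0.5 kPa and
RMSE < 1.5 kPa over 200 replicate sweeps) use a +70 kPa-intercept twin of the
reference model for which the floor never engages, isolating the estimator
from the censoring. What passing tests show, accordingly: the estimators are
correct and calibrated for the assumed Gaussian error model, and the pipeline
is decisive under study-like conditions — not that real digested-gel
measurements are homoscedastic, uncensored or fully crossed (the study's raw
table may well be irregular "historical data").

## Problem sizes and numerics

Simulation-based checks use the sizes stated above (756-row sweeps, 200
replicate fits, 100-seed diffusivity recoveries, 1000-point coverage runs,
500-campaign verification coverage with designs computed once and noise
vectorized) — comfortable desk-scale choices that leave Monte-Carlo noise far
inside the asserted margins. All reals are double precision; model JSON files
round-trip coefficients bit-exactly (CSV readers use round-trip float
parsing). Optimizer determinism comes from the fixed multistart order and
tie-break; every stochastic test and generator is seeded.

## Known limitations

* The quadratic is an interpolating surrogate: no physics constrains it
  outside the box, and it goes negative in one corner.
* No mixed-effects, heteroscedastic or transformed-response modelling; no
  automatic term selection; no D-optimal design generation.
* No multi-objective design (stiffness + printability jointly) and no
  robust/uncertainty-aware design beyond the prediction-interval report.
* No optical simulation of the projector and no absorber-concentration →
  D_p predictive model; per-level working curves only.
* Diffusion is 1-D, semi-infinite, constant-D; image processing to extract
  profiles is assumed done upstream.
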