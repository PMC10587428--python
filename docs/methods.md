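# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `tackit`.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Compartment models and corrections

Tissue kinetics follow the one-tissue model (parameters K₁ mL/min/g,
k₂ min⁻¹) and the irreversible two-tissue model (adds k₃ min⁻¹ for local
accumulation; no k₄, a reversible second tissue compartment is never used).
The measured regional curve mixes tissue and whole blood through the
vascular fraction V_b: (1−V_b)·C_t + V_b·C_b.  A single V_b mixing term
stands in for spillover/partial-volume effects in both directions; separate
geometric spillover factors are not modelled.

All curves are decay-corrected concentrations.  Physical decay
(¹¹C half-life fixed at 20.364 min) acts uniformly on every compartment, so
decay-corrected curves obey the decay-free kinetic equations; decay enters
only through the noise model, the fit weights, and the explicit
`decay_correct` operation (which multiplies/divides by e^(λ·t_mid) per
frame and guards against double application with a state tag).

Plasma metabolite correction multiplies the total plasma curve by a parent
fraction.  For the ketone tracer the labelled-CO₂ build-up is linear in
time; the printed slope 1.323 is interpreted as **percent per minute**
(fraction = 1.323·t/100, clamped at 1) — a fraction-per-minute reading
would exceed unity before the scan ends, so percent is the only consistent
unit.  For acetate the parent fraction is a user-configurable interpolation
table; the shipped default is a plausible literature-style healthy-adult
curve (1.0 at injection falling to 0.35 by 15 min) and is a configuration
default, not asserted ground truth.

### Convolution

Model curves are computed by exact convolution of a piecewise-linear input
against the exponential kernel on a uniform 0.5 s grid: each segment
contributes h[(c₀+c₁h)φ₁(kh) − c₁hφ₂(kh)] with φ₁ = (1−e⁻ˣ)/x,
φ₂ = (1−(1+x)e⁻ˣ)/x², switched to series below x ≈ 10⁻⁵/10⁻⁴ for numerical
stability, and the running state propagates through a one-pole recursion.
This is exact for the interpolant on the uneven frame grid (FFT convolution
is not) and the 2TC path reduces to the 1TC path identically at k₃ = 0.
Agreement with a stiff ODE oracle (LSODA, rtol 10⁻¹⁰) is verified to
relative error < 10⁻³ over random parameter draws.  Frames are reduced to
values by trapezoidal frame averaging on the same grid (exact for
piecewise-linear curves); the 0.5 s step divides every frame boundary.

## Synthetic data

The generator emulates image-derived regional TACs for the left-ventricle
blood pool, myocardium, renal cortex and renal pelvis under the 26-frame
30-min schedule (12×10 s, 6×30 s, 6×150 s, 2×300 s).

**Input function.**  A Feng-type tri-exponential bolus with arrival delay
τ = 0.25 min, eigenvalues (−4, −0.5, −0.015) min⁻¹ and amplitudes chosen so
the blood-pool peak is ~78 kBq/mL at ~0.5 min — an SUV near 17 for a
319 MBq dose in a 70 kg adult, the magnitude seen in healthy left-ventricle
curves.  Per subject the amplitudes scale with injected dose and body
weight plus a 5% lognormal jitter.  Whole blood equals plasma (no red-cell
partitioning; a configurable ratio is future work).  Real input functions
are image-derived and noisy; the simulator's are exact, which makes
parameter recovery cleaner than on real data (see Limitations).

**Organ truths.**  Kinetic parameters are drawn per subject from normal
distributions with the healthy-cohort reference means and SDs, truncated to
physiological ranges: myocardium K₁ 0.61(0.07)/0.69(0.10), k₂
0.063(0.021)/0.081(0.022) for AcAc/Ac with V_b ~ N(0.30, 0.05); renal
cortex follows the irreversible two-tissue truth for AcAc
(K₁ 0.87(0.10), k₂ 0.37(0.06), k₃ 0.021(0.015)) and one-tissue for Ac
(1.77(0.43), 0.21(0.02)), with V_b = 0.10.  Vitals: HR ~ N(65, 8) bpm,
SBP ~ N(115, 10) mmHg, dose ~ N(319, 53) MBq, weight ~ N(70, 10) kg.

**Renal pelvis.**  Vascular transit (blood curve × fraction ~ N(0.30,
0.05)) plus, for the ketone tracer only, a delayed gamma-variate
g(t) = A·(t/t_p)^α·e^(α(1−t/t_p)) peaking at amplitude A at mode t_p.  The
cohort draws A ~ N(38.6, 31.5) SUV (converted per subject through
dose/weight) and t_p ~ N(6.63, 3.13) min truncated at ≥3 min; the shape
α = 6 keeps the first post-injection minute clean so the early vascular
peak and the delayed excretion peak remain distinct, matching the observed
two-peak morphology.  The delayed mode is configurable (the underlying
report gives both ~7.1 min in text and 6.63 mean in its table, so no single
value is asserted).

**Noise.**  Zero-mean Gaussian with SD = scale·sqrt(max(v,0)·e^(λ·t_mid)/Δt)
(Δt in minutes): variance proportional to activity and the decay factor,
inversely proportional to frame duration — count statistics propagated
through decay correction.  The default scale 0.05 puts ~1.7% noise on early
10-s myocardial frames and ~0.7% on late 300-s frames.  All randomness in a
cohort flows from one seeded generator; a fixed seed gives bit-identical
output.

## Fitting

Weighted nonlinear least squares (trust-region reflective, bounds
K₁∈[0,5], k₂∈[0,2], k₃∈[0,1], V_b∈[0,1]) over the frames fully inside the
0–15 min window (22 of 26 frames): the ¹¹C signal has decayed through most
of a half-life by then and later frames carry little information.  Default
weights w = Δt·e^(−λ·t_mid) follow the count-statistics pattern (longer,
earlier frames weigh more); uniform weighting is available.  Five starts
(the configured initial point plus four seeded jittered restarts) guard
against local minima; the best weighted RSS wins, so results are
deterministic given the config seed.  V_b is fitted for the myocardium but
fixed (default 0.10) for the renal cortex, where careful segmentation away
from large vessels implies a small, poorly identified vascular term — this
is configuration, not an identified truth.  AIC uses the least-squares
convention n·ln(RSS/n) + 2p (AICc optional); only differences between
models fitted to the same data are meaningful.

## Derived metrics

- SUV = C/(dose/weight), dose in kBq and weight in g (unit density).
- RPP = HR·SBP/10⁴ and K₁ˢ = K₁/RPP.  The customary formula divides
  HR·SBP by 10³, but only 10⁴ is dimensionally consistent with scaled
  uptake values that stay on the K₁ scale (0.61 → ~0.81 at a resting RPP of
  ~0.75); the package uses 10⁴ and records the discrepancy here.
- MVO₂ = (1.35·k₂ − 9.6×10⁻³)·100, per 100 g, floored at 0 (the affine map
  is negative below k₂ ≈ 0.007 min⁻¹).
- MBF inverts K₁ = MBF·(1 − a·e^(−b/MBF)) by bracketed root-finding
  (tolerance 10⁻¹⁰); the extraction constants default to a = 0.64,
  b = 1.20 — a literature-style acetate parameterisation exposed as
  configuration, not asserted ground truth.
- Percent tracer differences are |x−ref|/ref·100 **relative to the acetate
  value**, with the direction and reference recorded in the result; this
  single convention reproduces all the published percent statements
  (heart k₂ 22%, cortex K₁ 53%, cortex k₂ ~46%).
- Between-organ folds are reported in both conventions (mean ± SD of
  per-subject ratios, and ratio of cohort means) because they differ and
  published fold statements mix them.
- The pelvis early-window summary ("sum over 0–2 min of the SUV frames") is
  a package-defined convenience with a configurable window; its upstream
  definition is unknown and it is excluded from any validation claims.

## Cohort statistics

Paired Student's t (or Wilcoxon signed-rank) for tracer contrasts; Pearson
correlation; within-subject one-way ANOVA with Tukey's HSD computed from
the repeated-measures error mean square (the Prism-style procedure).
Normality is asserted by configuration, never inferred.  Significance
markers use the tiers ≤0.05, ≤0.01, ≤0.001.  The RM-ANOVA decomposition is
cross-checked in the tests against `statsmodels.AnovaRM` and a permutation
oracle; paired tests and correlations are `scipy.stats` with degenerate
cases (zero-variance differences) flagged explicitly.

## Problem sizes

The test suite and acceptance script use: 100 random parameter draws for
the ODE-oracle comparison; 200 noisy replicates per organ for recovery
bias; a 10-subject cohort (the study's size) for the pipeline, summary
statistics and the AIC comparison; 2000 null simulations for type-I-error
calibration.  These sizes give Monte-Carlo standard errors comfortably
below the tolerances they are checked against.

## Known limitations

- **What passing tests show.**  The generator produces clean Feng-type
  inputs, exact compartment kinetics and uncorrelated Gaussian frame noise.
  Passing recovery tests therefore demonstrates correctness of the
  estimator, not expected accuracy on real data, which carries
  image-derived input error, motion, partial-volume and segmentation
  effects.
- **Model-selection behaviour.**  On synthetic cortex data generated with
  the reference k₃ ≈ 0.021, the irreversible 2TC model is usually AIC-
  preferred over 1TC (the extra parameter is genuinely identifiable when
  frame noise is the only residual source, at any realistic noise scale).
  On real data the two models were reported statistically equivalent —
  plausibly because shared unmodelled residuals raise both models' RSS
  floors.  The package reports the ΔAIC distribution rather than forcing
  agreement; simulating correlated model-mismatch residuals is out of
  scope.
- Simulated myocardial SUV peaks (~8) are lower than published
  left-ventricle ROI values (~17), which are blood-pool-dominated in early
  frames; the blood-pool region itself reproduces the published magnitude
  and peak time.
- No image-space simulation (voxels, resolution, sinograms), no DICOM, no
  gated/function analysis, no graphical (Patlak/Logan) methods.
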