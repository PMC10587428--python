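# tackit — dual-tracer PET kinetics of the heart and kidney

`tackit` is an analysis package for dynamic PET studies that compare the
ketone tracer ¹¹C-acetoacetate (AcAc) with ¹¹C-acetate (Ac) in the
myocardium and kidney of the same subjects.  It provides everything needed
to exercise and validate such an analysis without scan data: a synthetic
cohort generator with known kinetic ground truth, compartment-model fitting
with the standard signal corrections, the derived physiological metrics, and
the paired cohort statistics.

## The model

Regional time-activity curves C(t) (decay-corrected kBq/mL, averaged over
the acquisition frames 12×10 s, 6×30 s, 6×150 s, 2×300 s) are described by
compartment models driven by the metabolite-corrected plasma input Cp and
mixed with whole blood C_b through the vascular fraction V_b:

- **one-tissue (1TC)**: dC_t/dt = K₁·Cp − k₂·C_t
- **irreversible two-tissue (2TC)**: dC₁/dt = K₁·Cp − (k₂+k₃)·C₁,
  dC₂/dt = k₃·C₁, C_t = C₁ + C₂

measured curve = (1−V_b)·C_t + V_b·C_b.  K₁ (mL/min/g) is perfusion-related
uptake, k₂ (min⁻¹) clearance (oxidative metabolism for acetate), k₃ (min⁻¹)
irreversible local accumulation.  Curves are computed by exact convolution
of a piecewise-linear input with the exponential kernels, fitted by weighted
nonlinear least squares over the first 15 min, and compared with
AIC = n·ln(RSS/n) + 2p.

Derived metrics: SUV = C/(dose/weight); K₁ˢ = K₁/RPP with
RPP = HR·SBP/10⁴; MVO₂ = (1.35·k₂ − 9.6×10⁻³)·100 mL/100 g/min;
MBF solves the Renkin-Crone relation K₁ = MBF·(1 − a·e^(−b/MBF)).
The renal pelvis is modelled as vascular transit plus, for AcAc only, a
delayed gamma-variate excretion peak (~7 min), and a peak detector separates
the two maxima.

## Worked example

```python
import tackit

schedule = tackit.default_frame_schedule()      # 26 frames, 0–1800 s
aif = tackit.FengInput()                      # synthetic bolus input
truth = tackit.KineticParams(K1=0.61, k2=0.063, Vb=0.3)
tac = tackit.simulate_tissue_tac(
    tackit.OrganTruth("myocardium", truth), aif, schedule,
    metabolites=tackit.LinearCO2Metabolites(),   # 1.323 %/min CO2 build-up
)
cp = tackit.metabolite_correct(aif, tackit.LinearCO2Metabolites())
fit = tackit.fit_model(tac, cp, aif, "1tc")
print(fit.params.K1, fit.params.k2)
```

prints `0.6100000000021638 0.06299999999999889` — the noiseless fit recovers
the generating K₁ = 0.61 mL/min/g and k₂ = 0.063 min⁻¹ to machine precision,
i.e. the estimator is exact when the model is.

The full study-shaped analysis is the numbered drivers:

```sh
cd analysis
python 01_simulate_cohort.py   # 10 subjects x 2 tracers -> results/tacs.csv ...
python 02_fit_kinetics.py      # 1TC/2TC fits + AIC      -> results/fits.csv
python 03_derive_metrics.py    # SUV, K1s, MBF, MVO2 ... -> results/metrics.csv
python 04_cohort_stats.py      # paired stats            -> results/cohort_summary.csv
```

`02_fit_kinetics.py` ends with (seed 11):

```
renal_cortex ac     1tc    1.848  0.212  0.000  0.100
             acac   1tc    0.811  0.289  0.000  0.100
                    2tc    0.871  0.351  0.021  0.100
```

the fitted cohort means: acetate cortical uptake roughly twice the ketone's,
and the 1TC fit of 2TC-generated data reproducing the characteristic
downward shift of K₁ and k₂ (0.87→0.81, 0.35→0.29).  `04_cohort_stats.py`
prints the summary table with paired-test significance markers against the
acetate arm, e.g. `renal_cortex K1_1tc acac: 0.811 (0.091)***`.

The same pipeline is scriptable as `tackit simulate|fit|derive|cohort|run`
(see `tackit run --help`).

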