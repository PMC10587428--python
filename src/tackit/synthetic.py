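"""Synthetic time-activity data with known kinetic truth.

Nothing downstream requires scan data: this module simulates image-derived
regional TACs for the left-ventricle blood pool, myocardium, renal cortex and
renal pelvis, for both tracers, under the 26-frame dynamic schedule, with the
generating kinetic parameters stored alongside.  Cohort defaults reproduce
the healthy-adult reference values (means/SDs) of the study population, so a
default cohort is a virtual re-run of the study with known ground truth.

Simulated concentrations are decay-corrected kBq/mL.  Noise is zero-mean
Gaussian with the standard PET TAC heteroscedasticity: variance proportional
to activity times the decay factor, inversely proportional to frame duration
(count statistics propagated through decay correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .aif import FengInput, FengParams, InputFunction
from .kinetics import (
    C11_HALFLIFE_MIN,
    KineticParams,
    MetaboliteModel,
    NoMetabolites,
    default_metabolite_model,
    forward_model,
)
from .metrics import SubjectVitals
from .schedule import FrameSchedule, TimeActivityCurve, fine_time_grid, frame_average, default_frame_schedule

__all__ = [
    "SecondPeak",
    "OrganTruth",
    "NoiseSpec",
    "simulate_tissue_tac",
    "simulate_pelvis_tac",
    "add_noise",
    "generate_cohort",
    "Cohort",
    "SubjectRecord",
    "RegionRecord",
    "reference_truth_distributions",
    "REGIONS",
    "TRACERS",
]

REGIONS = ("lv_blood", "myocardium", "renal_cortex", "renal_pelvis")
TRACERS = ("acac", "ac")


@dataclass(frozen=True)
class SecondPeak:
    """Delayed excretion component in the renal pelvis (gamma-variate).

    g(t) = amplitude * (t/mode)^shape * exp(shape * (1 - t/mode)), normalised
    so the curve peaks at ``amplitude`` exactly at t = ``mode_min``.  Seen
    with acetoacetate only (pelvic appearance of secondary labelled species).
    """

    amplitude: float  # kBq/mL at the mode
    mode_min: float  # time of the maximum, minutes
    shape: float = 6.0  # sharpness; 6 keeps the first post-injection minute clean

    def __post_init__(self) -> None:
        if self.mode_min <= 0:
            raise ValueError("second-peak mode time must be positive")
        if self.amplitude < 0 or self.shape <= 0:
            raise ValueError("amplitude must be >= 0 and shape > 0")

    def __call__(self, t_min: np.ndarray) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        x = np.maximum(t, 0.0) / self.mode_min
        return self.amplitude * np.power(x, self.shape) * np.exp(self.shape * (1.0 - x))


@dataclass(frozen=True)
class OrganTruth:
    """Generating truth for one region: kinetic params and, for the pelvis,
    the vascular fraction and optional delayed second peak."""

    region: str
    params: KineticParams
    early_fraction: float = 0.0  # pelvis: vascular scaling of the blood curve
    second_peak: SecondPeak | None = None

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.second_peak is not None and self.region != "renal_pelvis":
            raise ValueError("second peak is a renal-pelvis feature")
        if not 0.0 <= self.early_fraction <= 1.0:
            raise ValueError("early_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class NoiseSpec:
    """Frame-weighted Gaussian noise: SD = scale * sqrt(v * e^{lam*t} / dt)."""

    scale: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValueError("noise scale must be non-negative")


def simulate_tissue_tac(
    truth: OrganTruth,
    aif: InputFunction,
    schedule: FrameSchedule,
    metabolites: MetaboliteModel | None = None,
    step_s: float = 0.5,
) -> TimeActivityCurve:
    """Noiseless tissue TAC: frame averages of (1-Vb)*Ct + Vb*Cb.

    The tissue compartment is driven by the parent-plasma curve (the total
    input times the metabolite parent fraction); the blood term uses the
    total whole-blood curve.  Whole blood equals plasma by default (no
    red-cell partitioning).
    """
    metabolites = metabolites or NoMetabolites()
    t = fine_time_grid(schedule, step_s)
    cb = aif(t)
    cp = cb * metabolites.parent_fraction(t)
    curve = forward_model(truth.params, cp, cb, t)
    values = frame_average(t, curve, schedule)
    return TimeActivityCurve(schedule, values, meta={"region": truth.region})


def simulate_pelvis_tac(
    truth: OrganTruth,
    aif: InputFunction,
    schedule: FrameSchedule,
    step_s: float = 0.5,
) -> TimeActivityCurve:
    """Renal-pelvis TAC: early vascular transit plus optional delayed peak.

    The early component is the blood curve scaled by ``early_fraction``; the
    delayed component is the gamma-variate ``second_peak`` (acetoacetate
    only).  Two local maxima appear when the delayed amplitude exceeds the
    vascular tail at the second mode.
    """
    if truth.region != "renal_pelvis":
        raise ValueError("simulate_pelvis_tac requires region = renal_pelvis")
    t = fine_time_grid(schedule, step_s)
    curve = truth.early_fraction * aif(t)
    if truth.second_peak is not None:
        curve = curve + truth.second_peak(t)
    values = frame_average(t, curve, schedule)
    return TimeActivityCurve(schedule, values, meta={"region": "renal_pelvis"})


def add_noise(
    tac: TimeActivityCurve,
    spec: NoiseSpec,
    halflife_min: float = C11_HALFLIFE_MIN,
    rng: np.random.Generator | None = None,
) -> TimeActivityCurve:
    """Add frame-weighted Gaussian noise, reproducible under a fixed seed.

    SD_i = scale * sqrt(max(v_i, 0) * exp(lam * t_mid,i) / dt_i) with dt in
    minutes: late (decayed) and short frames are noisier, matching PET ROI
    count statistics after decay correction.
    """
    lam = np.log(2.0) / halflife_min
    sd = spec.scale * np.sqrt(
        np.maximum(tac.values, 0.0) * np.exp(lam * tac.t_mid_min) / tac.schedule.duration_min
    )
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    return tac.with_values(tac.values + rng.normal(0.0, 1.0, tac.values.size) * sd)


# ---------------------------------------------------------------------------
# cohort generation


def reference_truth_distributions() -> dict:
    """Default truth distributions: healthy-cohort means (SDs), truncated at 0.

    Myocardium and acetate cortex follow one-tissue truths; acetoacetate
    cortex follows the irreversible two-tissue truth (K1 0.87, k2 0.37,
    k3 0.021) so that both candidate models can be confronted with it.
    Pelvis second-peak amplitude is parameterised in SUV (converted per
    subject through dose/weight) with mode time ~6.6 min.
    """
    return {
        ("myocardium", "acac"): {"K1": (0.61, 0.07), "k2": (0.063, 0.021), "k3": (0.0, 0.0), "Vb": (0.30, 0.05)},
        ("myocardium", "ac"): {"K1": (0.69, 0.10), "k2": (0.081, 0.022), "k3": (0.0, 0.0), "Vb": (0.30, 0.05)},
        ("renal_cortex", "acac"): {"K1": (0.87, 0.10), "k2": (0.37, 0.06), "k3": (0.021, 0.015), "Vb": (0.10, 0.0)},
        ("renal_cortex", "ac"): {"K1": (1.77, 0.43), "k2": (0.21, 0.02), "k3": (0.0, 0.0), "Vb": (0.10, 0.0)},
        ("renal_pelvis", "acac"): {
            "early_fraction": (0.30, 0.05),
            "second_suv": (38.6, 31.5),
            "second_mode_min": (6.63, 3.13),
        },
        ("renal_pelvis", "ac"): {"early_fraction": (0.30, 0.05)},
        "vitals": {
            "hr": (65.0, 8.0),
            "sbp": (115.0, 10.0),
            "dose_mbq": (319.0, 53.0),
            "weight_kg": (70.0, 10.0),
        },
    }


#: physiological truncation bounds used when drawing truths/vitals
_TRUNC = {
    "K1": (1e-3, 5.0),
    "k2": (1e-3, 2.0),
    "k3": (0.0, 1.0),
    "Vb": (0.02, 0.6),
    "early_fraction": (0.05, 0.8),
    "second_suv": (2.0, 200.0),
    "second_mode_min": (3.0, 15.0),
    "hr": (40.0, 110.0),
    "sbp": (85.0, 160.0),
    "dose_mbq": (100.0, 600.0),
    "weight_kg": (45.0, 110.0),
}


def _draw(rng: np.random.Generator, mean: float, sd: float, key: str) -> float:
    if sd < 0:
        raise ValueError(f"negative SD for {key}")
    lo, hi = _TRUNC[key]
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise ValueError(f"truncated draw for {key} did not converge; check distribution")


@dataclass(frozen=True)
class RegionRecord:
    tac: TimeActivityCurve
    truth: OrganTruth


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    vitals: SubjectVitals
    aif_params: dict  # tracer -> FengParams
    regions: dict  # (tracer, region) -> RegionRecord


@dataclass(frozen=True)
class Cohort:
    subjects: list
    schedule: FrameSchedule
    seed: int
    noise: NoiseSpec


def generate_cohort(
    n: int,
    truth_distributions: dict | None = None,
    seed: int = 0,
    noise_scale: float = 0.05,
    schedule: FrameSchedule | None = None,
    tracers: tuple = TRACERS,
    base_aif: FengParams | None = None,
    metabolite_models: dict | None = None,
) -> Cohort:
    """Virtual cohort: per subject, vitals plus per-tracer regional TACs with truth.

    All randomness flows from ``seed`` through one generator, so a fixed seed
    yields bit-identical cohorts.  Per-subject input functions scale the base
    bolus by injected dose and body weight (keeping SUV magnitudes realistic)
    with a small lognormal shape jitter.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    dists = truth_distributions or reference_truth_distributions()
    schedule = schedule or default_frame_schedule()
    base_aif = base_aif or FengParams()
    metabolite_models = metabolite_models or {tr: default_metabolite_model(tr) for tr in tracers}
    rng = np.random.default_rng(seed)
    noise = NoiseSpec(scale=noise_scale, seed=seed)

    subjects = []
    for i in range(n):
        vit = {k: _draw(rng, *dists["vitals"][k], k) for k in ("hr", "sbp", "dose_mbq", "weight_kg")}
        vitals = SubjectVitals(**vit)
        suv_norm = vitals.dose_mbq / vitals.weight_kg  # kBq/mL per SUV
        aif_params = {}
        regions = {}
        for tracer in tracers:
            scale = (vitals.dose_mbq / 319.0) * (70.0 / vitals.weight_kg)
            scale *= float(np.exp(rng.normal(0.0, 0.05)))
            p = base_aif.scaled(scale)
            aif_params[tracer] = p
            aif = FengInput(p)
            metab = metabolite_models.get(tracer, NoMetabolites())

            # blood pool: the measured LV region is (modelled as) pure blood
            blood_truth = OrganTruth("lv_blood", KineticParams(0.0, 0.0, 0.0, 1.0))
            tacs = {"lv_blood": simulate_tissue_tac(blood_truth, aif, schedule)}
            truths = {"lv_blood": blood_truth}

            for region in ("myocardium", "renal_cortex"):
                d = dists[(region, tracer)]
                params = KineticParams(
                    K1=_draw(rng, *d["K1"], "K1"),
                    k2=_draw(rng, *d["k2"], "k2"),
                    k3=_draw(rng, *d["k3"], "k3") if d["k3"][0] > 0 or d["k3"][1] > 0 else 0.0,
                    Vb=_draw(rng, *d["Vb"], "Vb"),
                )
                truth = OrganTruth(region, params)
                tacs[region] = simulate_tissue_tac(truth, aif, schedule, metabolites=metab)
                truths[region] = truth

            d = dists[("renal_pelvis", tracer)]
            second = None
            if "second_suv" in d:
                second = SecondPeak(
                    amplitude=_draw(rng, *d["second_suv"], "second_suv") * suv_norm,
                    mode_min=_draw(rng, *d["second_mode_min"], "second_mode_min"),
                )
            pelvis_truth = OrganTruth(
                "renal_pelvis",
                KineticParams(0.0, 0.0, 0.0, 0.0),
                early_fraction=_draw(rng, *d["early_fraction"], "early_fraction"),
                second_peak=second,
            )
            tacs["renal_pelvis"] = simulate_pelvis_tac(pelvis_truth, aif, schedule)
            truths["renal_pelvis"] = pelvis_truth

            for region, tac in tacs.items():
                tac.meta.update(subject_id=f"S{i + 1:02d}", tracer=tracer, region=region)
                if noise.scale > 0:
                    tac = add_noise(tac, noise, rng=rng)
                regions[(tracer, region)] = RegionRecord(tac=tac, truth=truths[region])

        subjects.append(
            SubjectRecord(subject_id=f"S{i + 1:02d}", vitals=vitals, aif_params=aif_params, regions=regions)
        )
    return Cohort(subjects=subjects, schedule=schedule, seed=seed, noise=noise)
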