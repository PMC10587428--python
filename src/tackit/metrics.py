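"""Per-subject derived quantities: SUV, peaks, RPP scaling, MVO2, MBF, ratios.

These are the scalar summaries reported per subject once kinetic fits exist:
standardized uptake values and their peaks, the rate-pressure-product-scaled
uptake rate, myocardial oxygen consumption from the acetate clearance rate,
myocardial blood flow from the acetate uptake rate via a Renkin-Crone
extraction model, and the between-organ/between-tracer ratio conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq
from scipy.signal import find_peaks

from .schedule import TimeActivityCurve

__all__ = [
    "SubjectVitals",
    "PeakRecord",
    "suv_curve",
    "peak_stats",
    "detect_peaks",
    "rate_pressure_product",
    "scaled_k1",
    "mvo2_from_k2",
    "mbf_from_k1_acetate",
    "k1_from_mbf_acetate",
    "kinetic_ratio",
    "fold_change",
    "percent_diff_vs_ref",
    "PercentDiff",
]


@dataclass(frozen=True)
class SubjectVitals:
    """Heart rate (bpm), systolic blood pressure (mmHg), injected dose (MBq),
    body weight (kg)."""

    hr: float
    sbp: float
    dose_mbq: float
    weight_kg: float

    def __post_init__(self) -> None:
        for name in ("hr", "sbp", "dose_mbq", "weight_kg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class PeakRecord(NamedTuple):
    suv_max: float
    t_max_min: float
    index: int  # 0 = first peak, 1 = second


def suv_curve(tac: TimeActivityCurve, vitals: SubjectVitals) -> TimeActivityCurve:
    """Normalise a kBq/mL TAC to SUV: C(t) / (injected activity / body mass).

    Dose in MBq converts to kBq, weight in kg to grams (unit tissue density),
    so the normaliser is dose*1000 / (weight*1000) = dose/weight kBq/g.
    """
    if tac.units != "kBq/mL":
        raise ValueError(f"expected kBq/mL TAC, got {tac.units!r}")
    factor = vitals.dose_mbq / vitals.weight_kg  # kBq/g
    return tac.with_values(tac.values / factor, units="SUV")


def peak_stats(tac: TimeActivityCurve) -> PeakRecord:
    """Global maximum frame value and its frame mid-time; ties -> earliest."""
    if tac.schedule.n_frames < 1:
        raise ValueError("empty TAC")
    i = int(np.argmax(tac.values))  # argmax returns the first maximum
    return PeakRecord(float(tac.values[i]), float(tac.t_mid_min[i]), 0)


def detect_peaks(tac: TimeActivityCurve, min_prominence: float = 0.5) -> list[PeakRecord]:
    """Interior local maxima with at least the given prominence, by time.

    At most the first two peaks are reported — the early vascular transit and
    (for acetoacetate in the renal pelvis) the delayed excretion signal.
    """
    if tac.schedule.n_frames < 3:
        raise ValueError("need at least 3 frames")
    idx, _ = find_peaks(tac.values, prominence=min_prominence)
    return [
        PeakRecord(float(tac.values[i]), float(tac.t_mid_min[i]), rank)
        for rank, i in enumerate(idx[:2])
    ]


def rate_pressure_product(vitals: SubjectVitals) -> float:
    """RPP = HR * SBP / 1e4, a dimensionless cardiac-workload index.

    The 1e4 scaling puts typical resting values near 0.75 so that the scaled
    uptake K1s = K1/RPP stays on the K1 scale (0.61 -> ~0.81 mL/min/g).
    """
    return vitals.hr * vitals.sbp / 1e4


def scaled_k1(k1: float, rpp: float) -> float:
    """Workload-scaled uptake rate K1s = K1 / RPP."""
    if rpp <= 0:
        raise ValueError("RPP must be positive")
    return k1 / rpp


def mvo2_from_k2(k2: float) -> float:
    """Myocardial oxygen consumption (mL O2/100 g/min) from acetate k2.

    The calibration MVO2 = 1.35*k2 - 9.6e-3 (per gram) maps the acetate
    clearance rate to oxidative flux; reported per 100 g and floored at 0.
    """
    if k2 < 0:
        raise ValueError("k2 must be non-negative")
    return max(1.35 * k2 - 9.6e-3, 0.0) * 100.0


#: Renkin-Crone extraction defaults for acetate (configurable literature
#: values, not asserted ground truth): E(MBF) = 1 - a*exp(-b/MBF).
RENKIN_CRONE_A = 0.64
RENKIN_CRONE_B = 1.20


def k1_from_mbf_acetate(mbf: float, a: float = RENKIN_CRONE_A, b: float = RENKIN_CRONE_B) -> float:
    """Forward Renkin-Crone map K1 = MBF * (1 - a*exp(-b/MBF))."""
    if not 0 < a < 1:
        raise ValueError("extraction parameter a must lie in (0, 1)")
    if b <= 0:
        raise ValueError("extraction parameter b must be positive")
    if mbf < 0:
        raise ValueError("MBF must be non-negative")
    if mbf == 0:
        return 0.0
    return mbf * (1.0 - a * np.exp(-b / mbf))


def mbf_from_k1_acetate(
    k1: float,
    a: float = RENKIN_CRONE_A,
    b: float = RENKIN_CRONE_B,
    mbf_max: float = 20.0,
) -> float:
    """Invert the Renkin-Crone map for myocardial blood flow (mL/min/g).

    The forward map is strictly increasing in MBF, so the root is bracketed
    and found to 1e-10 absolute tolerance.
    """
    if k1 <= 0:
        raise ValueError("K1 must be positive to invert for MBF (lower bound 0)")
    hi = k1_from_mbf_acetate(mbf_max, a, b)
    if k1 > hi:
        raise ValueError(
            f"K1 = {k1:g} exceeds the attainable K1 = {hi:g} at MBF = {mbf_max:g}; "
            "raise mbf_max"
        )
    return float(brentq(lambda f: k1_from_mbf_acetate(f, a, b) - k1, 1e-12, mbf_max, xtol=1e-10))


def kinetic_ratio(k1: float, k2: float) -> float:
    """Distribution-volume-like ratio K1/k2 (mL/g)."""
    if k2 <= 0:
        raise ValueError("k2 must be positive")
    return k1 / k2


def fold_change(x_organ: float, x_ref: float) -> float:
    """Ratio organ/reference (e.g. renal cortex over myocardium)."""
    if x_ref <= 0:
        raise ValueError("reference value must be positive")
    return x_organ / x_ref


class PercentDiff(NamedTuple):
    percent: float
    direction: str  # 'higher' or 'lower' than the reference
    reference: str


def percent_diff_vs_ref(x: float, ref: float, reference_label: str = "ac") -> PercentDiff:
    """Percent difference of ``x`` relative to the reference-tracer value.

    Always |x - ref| / ref * 100, with the direction recorded: this is the
    convention behind statements like "k2 was 22% higher for acetate" (heart)
    and "K1 was 53% higher" (cortex), both expressed against acetate.
    """
    if ref <= 0:
        raise ValueError("reference value must be positive")
    pct = abs(x - ref) / ref * 100.0
    direction = "lower" if x < ref else "higher"
    return PercentDiff(pct, direction, reference_label)
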