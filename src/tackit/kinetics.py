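"""Forward compartment models and signal corrections.

Two tracer models are used, both driven by the metabolite-corrected plasma
input Cp and mixed with whole-blood activity Cb through the fractional blood
volume Vb:

* one-tissue (1TC): dCt/dt = K1*Cp - k2*Ct, so
  Ct(t) = K1 * int_0^t Cp(s) exp(-k2 (t-s)) ds

* irreversible two-tissue (2TC): dC1/dt = K1*Cp - (k2+k3)*C1,
  dC2/dt = k3*C1, Ct = C1 + C2, equivalently
  Ct(t) = K1/(k2+k3) * [ k3 * int_0^t Cp + k2 * (Cp (*) exp(-(k2+k3)t)) ]

The measured regional curve is (1-Vb)*Ct + Vb*Cb.

Convolutions are computed exactly for a piecewise-linear Cp sampled on a
uniform fine grid: each segment's integral against the exponential kernel has
a closed form, and the running state is propagated by a one-pole recursion
(scipy.signal.lfilter).  This is accurate on the uneven frame grid where FFT
convolution is not, and all model curves (1TC, 2TC, the k3=0 nesting) share
the same code path.

All curves are decay-corrected concentrations: physical decay acts uniformly
on every compartment, so decay-corrected tissue and blood obey the decay-free
kinetic equations above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import lfilter

from .schedule import TimeActivityCurve

__all__ = [
    "KineticParams",
    "DecaySpec",
    "MetaboliteModel",
    "LinearCO2Metabolites",
    "TableMetabolites",
    "NoMetabolites",
    "C11_HALFLIFE_MIN",
    "exp_conv",
    "cumulative_integral",
    "model_1tc",
    "model_2tc_irr",
    "decay_correct",
    "metabolite_correct",
]

C11_HALFLIFE_MIN = 20.364  # physical half-life of carbon-11


@dataclass(frozen=True)
class KineticParams:
    """Compartment-model state: K1 (mL/min/g), k2, k3 (1/min), Vb (fraction).

    k3 = 0 identifies the one-tissue model.
    """

    K1: float
    k2: float
    k3: float = 0.0
    Vb: float = 0.0

    def __post_init__(self) -> None:
        if self.K1 < 0 or self.k2 < 0 or self.k3 < 0:
            raise ValueError("rate constants must be non-negative")
        if not 0.0 <= self.Vb <= 1.0:
            raise ValueError("Vb must lie in [0, 1]")

    @property
    def is_one_tissue(self) -> bool:
        return self.k3 == 0.0


@dataclass(frozen=True)
class DecaySpec:
    halflife_min: float = C11_HALFLIFE_MIN

    def __post_init__(self) -> None:
        if self.halflife_min <= 0:
            raise ValueError("halflife must be positive")

    @property
    def lam(self) -> float:
        """Decay constant (1/min)."""
        return np.log(2.0) / self.halflife_min


# ---------------------------------------------------------------------------
# exact convolution of a piecewise-linear function with exp(-k t)


def _phi1(x: np.ndarray) -> np.ndarray:
    """(1 - e^-x)/x, stable near 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-5
    xs = np.where(small, 1.0, x)
    out = (1.0 - np.exp(-xs)) / xs
    return np.where(small, 1.0 - x / 2.0 + x * x / 6.0, out)


def _phi2(x: np.ndarray) -> np.ndarray:
    """(1 - (1+x) e^-x)/x^2, stable near 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-4
    xs = np.where(small, 1.0, x)
    out = (1.0 - (1.0 + xs) * np.exp(-xs)) / (xs * xs)
    return np.where(small, 0.5 - x / 3.0 + x * x / 8.0, out)


def exp_conv(t_min: np.ndarray, f: np.ndarray, k: float) -> np.ndarray:
    """int_0^t f(s) exp(-k (t-s)) ds for piecewise-linear f on a uniform grid.

    Exact for the interpolant: each segment contributes
    h*[(c0 + c1 h) phi1(kh) - c1 h phi2(kh)] and the state decays by
    exp(-k h) per step.
    """
    t = np.asarray(t_min, dtype=float)
    f = np.asarray(f, dtype=float)
    if t.size != f.size or t.size < 2:
        raise ValueError("t and f must be matching arrays of length >= 2")
    h = t[1] - t[0]
    if not np.allclose(np.diff(t), h, rtol=1e-9, atol=1e-12):
        raise ValueError("exp_conv requires a uniform time grid")
    if k < 0:
        raise ValueError("k must be non-negative")
    c0 = f[:-1]
    c1 = (f[1:] - f[:-1]) / h
    x = k * h
    seg = h * ((c0 + c1 * h) * _phi1(x) - c1 * h * _phi2(x))
    decay = np.exp(-x)
    out = lfilter([1.0], [1.0, -decay], seg)
    return np.concatenate([[0.0], out])


def cumulative_integral(t_min: np.ndarray, f: np.ndarray) -> np.ndarray:
    """int_0^t f ds, trapezoidal (exact for piecewise-linear f)."""
    return np.concatenate([[0.0], cumulative_trapezoid(np.asarray(f, float), np.asarray(t_min, float))])


# ---------------------------------------------------------------------------
# forward models


def _mix_blood(ct: np.ndarray, cb: np.ndarray, vb: float) -> np.ndarray:
    return (1.0 - vb) * ct + vb * cb


def model_1tc(
    params: KineticParams,
    cp: np.ndarray,
    cb: np.ndarray,
    t_min: np.ndarray,
) -> np.ndarray:
    """One-tissue model curve (1-Vb)*Ct + Vb*Cb on the given uniform grid."""
    if params.k3 != 0.0:
        raise ValueError("one-tissue model requires k3 = 0")
    ct = params.K1 * exp_conv(t_min, cp, params.k2)
    return _mix_blood(ct, np.asarray(cb, float), params.Vb)


def model_2tc_irr(
    params: KineticParams,
    cp: np.ndarray,
    cb: np.ndarray,
    t_min: np.ndarray,
) -> np.ndarray:
    """Irreversible two-tissue model curve on the given uniform grid.

    k2 + k3 = 0 degenerates to pure trapping, Ct = K1 * int Cp.
    """
    k23 = params.k2 + params.k3
    if k23 <= 0.0:
        ct = params.K1 * cumulative_integral(t_min, cp)
    else:
        conv = exp_conv(t_min, cp, k23)
        if params.k3 == 0.0:
            ct = params.K1 * conv  # exact 1TC nesting, same convolution path
        else:
            acc = cumulative_integral(t_min, cp)
            ct = params.K1 / k23 * (params.k3 * acc + params.k2 * conv)
    return _mix_blood(ct, np.asarray(cb, float), params.Vb)


def forward_model(params: KineticParams, cp, cb, t_min) -> np.ndarray:
    """Dispatch on k3: the 1TC and irreversible 2TC curves coincide at k3=0."""
    return model_2tc_irr(params, cp, cb, t_min)


# ---------------------------------------------------------------------------
# decay correction


def decay_correct(
    tac: TimeActivityCurve,
    spec: DecaySpec = DecaySpec(),
    direction: str = "apply",
) -> TimeActivityCurve:
    """Apply or remove physical-decay correction at frame mid-times.

    ``apply`` multiplies by exp(lam * t_mid) (raw -> decay-corrected);
    ``remove`` divides.  The ``decay_corrected`` tag guards against double
    application.
    """
    if direction not in ("apply", "remove"):
        raise ValueError("direction must be 'apply' or 'remove'")
    if direction == "apply" and tac.decay_corrected:
        raise ValueError("TAC is already decay-corrected")
    if direction == "remove" and not tac.decay_corrected:
        raise ValueError("TAC is not decay-corrected")
    factor = np.exp(spec.lam * tac.t_mid_min)
    if direction == "apply":
        return tac.with_values(tac.values * factor, decay_corrected=True)
    return tac.with_values(tac.values / factor, decay_corrected=False)


# ---------------------------------------------------------------------------
# plasma metabolite correction


class MetaboliteModel:
    """Parent-fraction model: fraction of plasma activity that is intact tracer."""

    def parent_fraction(self, t_min: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class NoMetabolites(MetaboliteModel):
    def parent_fraction(self, t_min):
        return np.ones_like(np.asarray(t_min, dtype=float))


class LinearCO2Metabolites(MetaboliteModel):
    """Linear growth of labelled CO2 in plasma: f_met(t) = slope*t/100.

    The acetoacetate scans are corrected with a linear [^11C-CO2] model whose
    slope is given in percent of total plasma activity per minute (default
    1.323 %/min); a fraction-per-minute reading would exceed 100% within the
    scan, so percent units are the only consistent interpretation.  The
    metabolised fraction is clamped at 1.
    """

    def __init__(self, slope_percent_per_min: float = 1.323):
        if slope_percent_per_min < 0:
            raise ValueError("slope must be non-negative")
        self.slope = slope_percent_per_min

    def parent_fraction(self, t_min):
        t = np.asarray(t_min, dtype=float)
        f_met = np.minimum(self.slope * t / 100.0, 1.0)
        return 1.0 - f_met


class TableMetabolites(MetaboliteModel):
    """Parent fraction interpolated from a (time_min, parent_fraction) table.

    Used for acetate, whose metabolite build-up is taken from literature
    curves; the table is user-configurable (see ``tackit.io.read_metabolite_table``).
    """

    def __init__(self, t_min: np.ndarray, parent_fraction: np.ndarray):
        t = np.asarray(t_min, dtype=float)
        pf = np.asarray(parent_fraction, dtype=float)
        if t.shape != pf.shape or t.ndim != 1 or t.size < 2:
            raise ValueError("need matching 1-D arrays of length >= 2")
        if np.any(np.diff(t) <= 0):
            raise ValueError("table times must be strictly increasing")
        if np.any((pf < 0) | (pf > 1)):
            raise ValueError("parent fractions must lie in [0, 1]")
        if t[0] == 0 and not np.isclose(pf[0], 1.0):
            raise ValueError("parent fraction must be 1 at t = 0")
        self.t = t
        self.pf = pf

    def parent_fraction(self, t_min):
        return np.interp(np.asarray(t_min, dtype=float), self.t, self.pf, left=1.0)


#: Default acetate parent-fraction table (literature-style healthy-adult
#: curve; configurable, not asserted as ground truth).
DEFAULT_ACETATE_TABLE = (
    np.array([0.0, 1.0, 3.0, 5.0, 10.0, 15.0, 20.0, 30.0]),
    np.array([1.0, 0.98, 0.88, 0.75, 0.50, 0.35, 0.28, 0.20]),
)


def default_metabolite_model(tracer: str) -> MetaboliteModel:
    """Tracer-appropriate default: linear CO2 for AcAc, table for Ac."""
    if tracer == "acac":
        return LinearCO2Metabolites()
    if tracer == "ac":
        return TableMetabolites(*DEFAULT_ACETATE_TABLE)
    raise ValueError(f"unknown tracer {tracer!r}")


def metabolite_correct(cp_total, model: MetaboliteModel):
    """Parent-only plasma curve: Cp_total(t) * parent_fraction(t).

    ``cp_total`` may be an InputFunction (returns a corrected callable) or an
    array sampled on ``t_min`` (pass arrays via :func:`metabolite_correct_samples`).
    """
    from .aif import ScaledInput

    return ScaledInput(cp_total, model.parent_fraction)


def metabolite_correct_samples(t_min: np.ndarray, cp_total: np.ndarray, model: MetaboliteModel) -> np.ndarray:
    return np.asarray(cp_total, float) * model.parent_fraction(t_min)
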