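"""Kinetic parameter estimation by weighted nonlinear least squares.

Only the first 15 minutes of the dynamic scan enter the fit (the ^11C signal
has decayed through almost a half-life by then and late frames carry little
information), matching the analysis window of the underlying protocol.  The
objective is sum_i w_i (y_i - yhat_i(theta))^2 over the in-window frames,
with default weights w_i = dt_i * exp(-lam * t_mid,i): longer and earlier
frames — more recorded counts — weigh more, the inverse-variance pattern of
decay-corrected PET frame noise.

Model selection between the one-tissue and irreversible two-tissue models
uses the Akaike information criterion in the least-squares convention
AIC = n ln(RSS/n) + 2p; absolute values are convention-dependent, only
differences between models fitted to the same data are meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .aif import InputFunction
from .kinetics import C11_HALFLIFE_MIN, KineticParams, forward_model
from .schedule import FrameSchedule, TimeActivityCurve, fine_time_grid, frame_average

__all__ = ["FitConfig", "FitResult", "ModelComparison", "fit_model", "compute_aic", "compare_models"]


@dataclass(frozen=True)
class FitConfig:
    """Fit window, weighting, bounds, starts and determinism controls."""

    window_min: tuple = (0.0, 15.0)
    weights: str = "duration-decay"  # or "uniform"
    init: KineticParams = KineticParams(K1=0.5, k2=0.1, k3=0.01, Vb=0.3)
    bounds: dict = field(
        default_factory=lambda: {"K1": (0.0, 5.0), "k2": (0.0, 2.0), "k3": (0.0, 1.0), "Vb": (0.0, 1.0)}
    )
    fit_vb: bool = True
    fixed_vb: float = 0.10
    multi_start: int = 5
    seed: int = 0
    max_nfev: int = 400
    grid_step_s: float = 0.5
    halflife_min: float = C11_HALFLIFE_MIN

    def __post_init__(self) -> None:
        lo, hi = self.window_min
        if not 0 <= lo < hi:
            raise ValueError("fit window must be an increasing interval from >= 0")
        if self.weights not in ("duration-decay", "uniform"):
            raise ValueError("weights must be 'duration-decay' or 'uniform'")
        for name in ("K1", "k2", "k3", "Vb"):
            b = self.bounds[name]
            if not b[0] <= getattr(self.init, name) <= b[1]:
                raise ValueError(f"initial {name} outside bounds")


@dataclass(frozen=True)
class FitResult:
    params: KineticParams
    model: str  # '1tc' or '2tc'
    rss: float  # weighted residual sum of squares
    n: int  # frames used
    p: int  # free parameters
    aic: float
    converged: bool
    degenerate: bool
    residuals: np.ndarray
    weights: np.ndarray
    frame_index: np.ndarray
    cov: np.ndarray | None = None
    n_starts: int = 1


@dataclass(frozen=True)
class ModelComparison:
    delta_aic: float  # AIC(a) - AIC(b)
    preferred: str
    equivalent: bool
    threshold: float


def compute_aic(rss: float, n: int, p: int, corrected: bool = False) -> float:
    """AIC = n ln(RSS/n) + 2p (least-squares form); AICc adds the small-sample
    correction 2p(p+1)/(n-p-1)."""
    if n <= p:
        raise ValueError("need more frames than parameters")
    if rss < 0:
        raise ValueError("RSS must be non-negative")
    if rss == 0:
        warnings.warn("RSS = 0: AIC is -inf (perfect fit)", RuntimeWarning, stacklevel=2)
        return -np.inf
    aic = n * np.log(rss / n) + 2 * p
    if corrected:
        aic += 2 * p * (p + 1) / (n - p - 1)
    return float(aic)


def _window_frames(schedule: FrameSchedule, window_min: tuple) -> np.ndarray:
    lo_s, hi_s = window_min[0] * 60.0, window_min[1] * 60.0
    keep = (schedule.frame_start_s >= lo_s - 1e-9) & (schedule.frame_end_s <= hi_s + 1e-9)
    return np.flatnonzero(keep)


def _frame_weights(schedule: FrameSchedule, idx: np.ndarray, cfg: FitConfig) -> np.ndarray:
    if cfg.weights == "uniform":
        return np.ones(idx.size)
    lam = np.log(2.0) / cfg.halflife_min
    return schedule.duration_min[idx] * np.exp(-lam * schedule.mid_min[idx])


def _pack(params: KineticParams, model: str, cfg: FitConfig) -> np.ndarray:
    theta = [params.K1, params.k2]
    if model == "2tc":
        theta.append(params.k3)
    if cfg.fit_vb:
        theta.append(params.Vb)
    return np.array(theta)


def _unpack(theta: np.ndarray, model: str, cfg: FitConfig) -> KineticParams:
    k1, k2 = theta[0], theta[1]
    j = 2
    k3 = 0.0
    if model == "2tc":
        k3 = theta[j]
        j += 1
    vb = theta[j] if cfg.fit_vb else cfg.fixed_vb
    return KineticParams(K1=float(k1), k2=float(k2), k3=float(k3), Vb=float(min(max(vb, 0.0), 1.0)))


def _theta_bounds(model: str, cfg: FitConfig) -> tuple[np.ndarray, np.ndarray]:
    names = ["K1", "k2"] + (["k3"] if model == "2tc" else []) + (["Vb"] if cfg.fit_vb else [])
    lo = np.array([cfg.bounds[n][0] for n in names])
    hi = np.array([cfg.bounds[n][1] for n in names])
    return lo, hi


def fit_model(
    tac: TimeActivityCurve,
    cp: InputFunction,
    cb: InputFunction,
    model: str = "1tc",
    cfg: FitConfig = FitConfig(),
) -> FitResult:
    """Fit the chosen compartment model to a decay-corrected TAC.

    ``cp`` is the metabolite-corrected (parent) plasma curve, ``cb`` the
    whole-blood curve for the Vb term.  Multi-start: the configured initial
    point plus seeded jittered restarts; the best weighted RSS wins, making
    the result deterministic under a fixed config seed.  If no start
    converges the best attempt is returned flagged.
    """
    if model not in ("1tc", "2tc"):
        raise ValueError("model must be '1tc' or '2tc'")
    if not tac.decay_corrected:
        raise ValueError("TAC must be decay-corrected before fitting")
    idx = _window_frames(tac.schedule, cfg.window_min)
    if idx.size == 0:
        raise ValueError("no frames inside the fit window")
    sub = FrameSchedule(tac.schedule.frame_start_s[idx], tac.schedule.frame_end_s[idx])
    y = tac.values[idx]
    w = _frame_weights(tac.schedule, idx, cfg)
    sw = np.sqrt(w)

    # the input curves are fixed during optimisation: sample once
    t = fine_time_grid(sub, cfg.grid_step_s)
    cp_s = np.asarray(cp(t), dtype=float)
    cb_s = np.asarray(cb(t), dtype=float)

    def predict(theta: np.ndarray) -> np.ndarray:
        p = _unpack(theta, model, cfg)
        curve = forward_model(p, cp_s, cb_s, t)
        return frame_average(t, curve, sub)

    def resid(theta: np.ndarray) -> np.ndarray:
        return sw * (predict(theta) - y)

    lo, hi = _theta_bounds(model, cfg)
    theta0 = np.clip(_pack(cfg.init, model, cfg), lo, hi)
    rng = np.random.default_rng(cfg.seed)
    starts = [theta0]
    for _ in range(max(cfg.multi_start - 1, 0)):
        jit = theta0 * np.exp(rng.normal(0.0, 0.5, theta0.size)) + rng.normal(0.0, 0.02, theta0.size)
        starts.append(np.clip(jit, lo, hi))

    best = None
    any_converged = False
    for s in starts:
        sol = least_squares(resid, s, bounds=(lo, hi), max_nfev=cfg.max_nfev, xtol=1e-12, ftol=1e-12, gtol=1e-12)
        any_converged = any_converged or sol.status > 0
        if best is None or sol.cost < best.cost:
            best = sol

    params = _unpack(best.x, model, cfg)
    res = predict(best.x) - y
    rss = float(np.sum(w * res**2))
    p_free = best.x.size
    aic = compute_aic(max(rss, 0.0), idx.size, p_free) if rss > 0 else -np.inf
    degenerate = bool(
        params.K1 <= lo[0] + 1e-12 or not np.all(np.isfinite(best.x)) or np.allclose(y, 0.0)
    )
    cov = None
    try:
        jac = best.jac
        dof = idx.size - p_free
        if dof > 0 and np.all(np.isfinite(jac)):
            jtj_inv = np.linalg.pinv(jac.T @ jac)
            cov = jtj_inv * (2 * best.cost / dof)
    except (np.linalg.LinAlgError, ValueError):  # pragma: no cover
        cov = None
    return FitResult(
        params=params,
        model=model,
        rss=rss,
        n=int(idx.size),
        p=p_free,
        aic=aic,
        converged=any_converged,
        degenerate=degenerate,
        residuals=res,
        weights=w,
        frame_index=idx,
        cov=cov,
        n_starts=len(starts),
    )


def compare_models(fit_a: FitResult, fit_b: FitResult, threshold: float = 2.0) -> ModelComparison:
    """Delta-AIC comparison of two fits of the same data and window.

    |delta AIC| below the threshold (default 2, the usual rule of thumb)
    marks the models as statistically equivalent.
    """
    if fit_a.n != fit_b.n or not np.array_equal(fit_a.frame_index, fit_b.frame_index):
        raise ValueError("fits used different data or windows; AIC not comparable")
    delta = fit_a.aic - fit_b.aic
    preferred = fit_a.model if delta <= 0 else fit_b.model
    return ModelComparison(
        delta_aic=float(delta),
        preferred=preferred,
        equivalent=bool(abs(delta) < threshold),
        threshold=threshold,
    )
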