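"""Exponential fitting of arterial diameter waveforms.

Systolic dilatation is modelled as a single exponential rise,

    D_d(t) = A_d - B_d * exp(-(t - C_d) / T_d),

and diastolic relaxation as a bi-exponential decay,

    D_r(t) = A_r + B_R1 * exp(-(t - C_r) / T_R1)
                 + B_R2 * exp(-(t - C_r) / T_R2),

with a fast constant T_R1 and a slow constant T_R2 (T_R1 < T_R2 by
convention, enforced by relabelling after the fit).  The motivation is the
Zener spring-dashpot picture of the arterial wall, whose step response is a
sum of exponentials; the slow diastolic decay happens under minimal driving
pressure and is therefore the window most sensitive to intrinsic wall
properties.

Fitting minimises the sum of squared residuals with the Nelder-Mead simplex.
Time constants and amplitudes are optimised in log-space so they stay
positive; the vertical shift A and time shift C are unconstrained.  The
standard initialisation sets A and C to the midpoint of the diameter and
time ranges of the window, both amplitudes to the size of one pixel,
T_R2 to the duration of the relaxation window and T_R1 = T_R2 / 10.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "FitSettings", "DilatationFit", "RelaxationFit", "FitRecord",
    "dilatation_model", "relaxation_model", "default_init",
    "fit_dilatation", "fit_relaxation", "accept_fit", "fit_diameter_map",
]


def dilatation_model(t, a, b, c, tau):
    """Single-exponential rise toward asymptote ``a``."""
    t = np.asarray(t, dtype=float)
    return a - b * np.exp(-(t - c) / tau)


def relaxation_model(t, a, b1, b2, c, tau1, tau2):
    """Bi-exponential decay toward asymptote ``a``."""
    t = np.asarray(t, dtype=float)
    return a + b1 * np.exp(-(t - c) / tau1) + b2 * np.exp(-(t - c) / tau2)


@dataclass(frozen=True)
class FitSettings:
    """Optimizer, initialization and acceptance configuration.

    pixel_size : mm; initial value for the exponential amplitudes (one pixel)
        and the scale of the residual-based acceptance threshold.
    xatol, fatol, maxiter : Nelder-Mead stopping criteria.
    restarts : number of optimiser starts; starts beyond the first jitter
        the initial vector multiplicatively (log-normal on positive
        parameters) and the best final cost wins.
    jitter : log-sd of the restart perturbation.
    seed : seed of the restart jitter stream (fits are deterministic).
    rmse_factor : accept only fits with rmse <= rmse_factor * pixel_size.
    t2_bounds : plausibility interval for the slow constant T_R2, seconds.
    min_timescale_ratio : reject fits with T_R2 / T_R1 below this (the two
        timescales have collapsed and the decay is effectively
        mono-exponential).
    """

    pixel_size: float = 0.021
    xatol: float = 1e-8
    fatol: float = 1e-8
    maxiter: int = 2000
    restarts: int = 3
    jitter: float = 0.2
    seed: int = 0
    rmse_factor: float = 2.0
    t2_bounds: tuple[float, float] = (0.05, 10.0)
    min_timescale_ratio: float = 2.0

    def __post_init__(self):
        if not (self.pixel_size > 0 and self.maxiter > 0 and self.restarts > 0
                and self.xatol > 0 and self.fatol > 0 and self.jitter >= 0
                and self.rmse_factor > 0 and self.min_timescale_ratio > 0
                and 0 < self.t2_bounds[0] < self.t2_bounds[1]):
            raise ValueError("all FitSettings fields must be positive")


@dataclass
class DilatationFit:
    """Result of fitting the systolic rise: (A_d, B_d, C_d, T_d)."""

    a: float
    b: float
    c: float
    tau: float
    rmse: float
    converged: bool
    degenerate: bool = False
    n_samples: int = 0
    init: np.ndarray | None = None

    @property
    def params(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.tau])


@dataclass
class RelaxationFit:
    """Result of fitting the diastolic decay.

    ``tau1`` is the fast constant T_R1 and ``tau2`` the slow constant T_R2;
    ``tau1 < tau2`` always holds (labels are swapped after the fit if
    needed).  ``accepted`` is set by :func:`accept_fit`.
    """

    a: float
    b1: float
    b2: float
    c: float
    tau1: float
    tau2: float
    rmse: float
    converged: bool
    degenerate: bool = False
    accepted: bool = False
    reject_reasons: tuple[str, ...] = ()
    n_samples: int = 0
    init: np.ndarray | None = None

    @property
    def params(self) -> np.ndarray:
        return np.array([self.a, self.b1, self.b2, self.c,
                         self.tau1, self.tau2])


@dataclass
class FitRecord:
    """A fit with its (cross-section, cycle) provenance."""

    x: int
    cycle: int
    fit: RelaxationFit
    dilatation: DilatationFit | None = None


# --------------------------------------------------------------------------
# Initialization
# --------------------------------------------------------------------------

def default_init(samples, t, settings: FitSettings,
                 kind: str = "relaxation") -> np.ndarray:
    """Standard initial parameter vector for a fitting window.

    A (vertical shift) starts at the midpoint of the diameter range in the
    window and C (time shift) at the midpoint of the time range.  Every
    exponential amplitude starts at the size of one pixel.  For relaxation,
    T_R2 starts at the window duration and T_R1 at T_R2 / 10; for
    dilatation the rise constant starts at a quarter of the window duration.

    Returns ``[A, B, C, T]`` for ``kind="dilatation"`` or
    ``[A, B1, B2, C, T1, T2]`` for ``kind="relaxation"``.
    """
    samples = np.asarray(samples, dtype=float)
    t = np.asarray(t, dtype=float)
    if samples.size < 4:
        raise ValueError("fitting window needs at least 4 samples")
    if samples.shape != t.shape:
        raise ValueError("samples and t must have the same shape")
    a0 = 0.5 * (np.nanmin(samples) + np.nanmax(samples))
    c0 = 0.5 * (t[0] + t[-1])
    b0 = settings.pixel_size
    duration = float(t[-1] - t[0])
    if duration <= 0:
        raise ValueError("window has zero duration")
    if kind == "dilatation":
        return np.array([a0, b0, c0, duration / 4.0])
    if kind == "relaxation":
        return np.array([a0, b0, b0, c0, duration / 10.0, duration])
    raise ValueError(f"unknown kind {kind!r}")


# --------------------------------------------------------------------------
# Nelder-Mead fitting
# --------------------------------------------------------------------------

_LOG_IDX = {"dilatation": [1, 3], "relaxation": [1, 2, 4, 5]}


def _to_internal(theta, kind):
    z = np.array(theta, dtype=float)
    idx = _LOG_IDX[kind]
    z[idx] = np.log(np.maximum(z[idx], 1e-300))
    return z


def _from_internal(z, kind):
    theta = np.array(z, dtype=float)
    idx = _LOG_IDX[kind]
    theta[idx] = np.exp(np.clip(theta[idx], -700, 700))
    return theta


def _sse(theta, t, samples, kind):
    if kind == "dilatation":
        pred = dilatation_model(t, *theta)
    else:
        pred = relaxation_model(t, *theta)
    r = pred - samples
    return float(np.dot(r, r))


def _run_nelder_mead(samples, t, init, kind, settings):
    """Multi-restart Nelder-Mead in the log-transformed parameter space."""
    rng = np.random.default_rng(settings.seed)
    n_pos = len(_LOG_IDX[kind])
    t_scale = max(float(t[-1] - t[0]), 1e-12)
    best = None
    for r in range(settings.restarts):
        theta0 = np.array(init, dtype=float)
        if r > 0 and settings.jitter > 0:
            theta0[_LOG_IDX[kind]] *= np.exp(
                rng.normal(0.0, settings.jitter, size=n_pos))
            theta0[0] += rng.normal(0.0, settings.jitter * settings.pixel_size)
            theta0[-3 if kind == "relaxation" else -2] += rng.normal(
                0.0, settings.jitter * t_scale)
        res = minimize(
            lambda z: _sse(_from_internal(z, kind), t, samples, kind),
            _to_internal(theta0, kind),
            method="Nelder-Mead",
            options={"xatol": settings.xatol, "fatol": settings.fatol,
                     "maxiter": settings.maxiter, "maxfev": 4 * settings.maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = _from_internal(best.x, kind)
    rmse = float(np.sqrt(best.fun / len(samples)))
    return theta, rmse, bool(best.success)


def fit_dilatation(samples, t, init=None,
                   settings: FitSettings = FitSettings()) -> DilatationFit:
    """Fit the single-exponential systolic rise to a dilatation window.

    ``init`` defaults to :func:`default_init`.  A fit whose amplitude is
    below a tenth of a pixel carries no rise information; it is flagged
    ``degenerate`` (the time constant is then unidentifiable).
    """
    samples = np.asarray(samples, dtype=float)
    t = np.asarray(t, dtype=float)
    if init is None:
        init = default_init(samples, t, settings, kind="dilatation")
    theta, rmse, ok = _run_nelder_mead(samples, t, init, "dilatation", settings)
    a, b, c, tau = theta
    degenerate = b < 0.1 * settings.pixel_size
    return DilatationFit(a=a, b=b, c=c, tau=tau, rmse=rmse, converged=ok,
                         degenerate=degenerate, n_samples=len(samples),
                         init=np.asarray(init, dtype=float))


def fit_relaxation(samples, t, init=None,
                   settings: FitSettings = FitSettings()) -> RelaxationFit:
    """Fit the bi-exponential diastolic decay to a relaxation window.

    After convergence the two time constants are relabelled so that
    ``tau1 < tau2`` (fast, slow), whatever their ordering in the initial
    vector.  A fit where the timescales collapse onto each other, or where
    one amplitude vanishes, is flagged ``degenerate`` — the decay is then
    effectively mono-exponential and carries no two-timescale information.
    """
    samples = np.asarray(samples, dtype=float)
    t = np.asarray(t, dtype=float)
    if init is None:
        init = default_init(samples, t, settings, kind="relaxation")
    theta, rmse, ok = _run_nelder_mead(samples, t, init, "relaxation", settings)
    a, b1, b2, c, tau1, tau2 = theta
    if tau1 > tau2:  # relabel fast/slow
        tau1, tau2 = tau2, tau1
        b1, b2 = b2, b1
    collapse = tau2 / tau1 < settings.min_timescale_ratio
    tiny = min(b1, b2) < 0.1 * settings.pixel_size
    return RelaxationFit(a=a, b1=b1, b2=b2, c=c, tau1=tau1, tau2=tau2,
                         rmse=rmse, converged=ok,
                         degenerate=bool(collapse or tiny),
                         n_samples=len(samples),
                         init=np.asarray(init, dtype=float))


def accept_fit(fit: RelaxationFit,
               settings: FitSettings = FitSettings()) -> RelaxationFit:
    """Apply the fit-rejection rules and return the fit with verdict attached.

    A relaxation fit is rejected when the optimiser did not converge, the
    residual exceeds ``rmse_factor`` pixels, the slow constant falls outside
    the plausibility bounds, or the two timescales collapse (ratio below
    ``min_timescale_ratio``) — the data were then not well fitted by a
    two-timescale decay and are excluded from further analysis.
    """
    reasons: list[str] = []
    if not fit.converged:
        reasons.append("not converged")
    if fit.rmse > settings.rmse_factor * settings.pixel_size:
        reasons.append("rmse")
    lo, hi = settings.t2_bounds
    if not (lo <= fit.tau2 <= hi):
        reasons.append("T_R2 out of bounds")
    if fit.tau2 / fit.tau1 < settings.min_timescale_ratio:
        reasons.append("timescale collapse")
    return replace(fit, accepted=not reasons, reject_reasons=tuple(reasons))


def fit_diameter_map(dmap, windows_by_x: dict[int, list],
                     settings: FitSettings = FitSettings(),
                     fit_dilatation_too: bool = False) -> list[FitRecord]:
    """Fit every (cross-section, cycle) relaxation window of a diameter map.

    ``windows_by_x`` maps a cross-section index (position in ``dmap.x_px``)
    to its detected cycle windows.  Cells masked by QC are dropped from the
    window before fitting; windows left with fewer than 4 finite samples are
    skipped.  Returns one accepted-or-rejected :class:`FitRecord` per
    fitted window.
    """
    records: list[FitRecord] = []
    t = dmap.t
    for ix, windows in windows_by_x.items():
        wave = dmap.d[ix]
        for k, w in enumerate(windows):
            sl = slice(w.peak, w.next_trough + 1)
            seg, tt = wave[sl], t[sl]
            good = np.isfinite(seg)
            if good.sum() < 4:
                continue
            fit = accept_fit(fit_relaxation(seg[good], tt[good],
                                            settings=settings), settings)
            dil = None
            if fit_dilatation_too:
                sl = slice(w.trough, w.peak + 1)
                seg, tt = wave[sl], t[sl]
                good = np.isfinite(seg)
                if good.sum() >= 4:
                    dil = fit_dilatation(seg[good], tt[good], settings=settings)
            records.append(FitRecord(x=int(dmap.x_px[ix]), cycle=k,
                                     fit=fit, dilatation=dil))
    return records
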