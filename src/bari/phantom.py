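"""Ground-truthed synthetic vessel phantoms.

Two levels of synthesis make every pipeline stage testable without clinical
recordings:

* :func:`simulate_diameter_trace` builds a diameter waveform directly from
  the exponential forward model — a steep systolic rise per cycle followed
  by a fast-then-slow bi-exponential diastolic decay — with known
  parameters and optional additive Gaussian noise.
* :func:`simulate_cine` rasterises that waveform into a B-mode-like cine
  loop: a dark lumen band between two bright wall bands in a speckled
  tissue background.  Speckle is the standard first-order model — a
  multiplicative Rayleigh-distributed envelope — plus additive Gaussian
  electronic noise.  Wall edges are anti-aliased so the true sub-pixel
  positions are well defined.

Both generators are pure functions of ``(spec, seed)``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .cine_io import CineLoop
from .fitting import dilatation_model, relaxation_model

__all__ = [
    "CycleParams", "PhantomSpec", "GroundTruth",
    "simulate_diameter_trace", "simulate_cine", "inject_lumen_artefact",
    "rayleigh_speckle", "recovery_experiment", "wall_error_experiment",
]


@dataclass(frozen=True)
class CycleParams:
    """True forward-model parameters of one cardiac cycle (mm, s).

    ``a_d`` is the systolic asymptote; ``a_r`` the end-diastolic asymptote;
    ``b_r1``/``b_r2`` the fast/slow decay amplitudes (their ratio is kept,
    the sum is re-solved for continuity at the systolic peak); ``tau_d``
    the rise constant; ``tau_r1 < tau_r2`` the fast and slow relaxation
    constants.
    """

    a_d: float = 3.8
    b_d: float = 0.8
    tau_d: float = 0.25  # comparable to the upstroke duration, so the
    # systolic peak stays peaked instead of plateauing at the asymptote
    a_r: float = 3.0
    b_r1: float = 0.5
    b_r2: float = 0.3
    tau_r1: float = 0.08
    tau_r2: float = 1.2


@dataclass
class PhantomSpec:
    """Everything that defines a phantom recording.

    Timing defaults reproduce a four-cycle loop with systolic peaks at
    0.5, 1.5, 3.0 and 4.0 s (note the irregular beat-to-beat spacing of a
    real recording).  Pixel spacing defaults to 21 um, the voxel size of
    the clinical recordings this phantom emulates.  ``speckle_contrast``
    in [0, 1] blends a unit-mean Rayleigh envelope into the echogenic
    bands (0 = noiseless, 1 = fully developed speckle).
    """

    peak_times: tuple[float, ...] = (0.5, 1.5, 3.0, 4.0)
    trough_times: tuple[float, ...] = (0.2, 1.2, 2.7, 3.7, 4.7)
    frame_rate: float = 50.0
    duration: float = 5.0
    cycle: CycleParams = field(default_factory=CycleParams)
    pixel_spacing: tuple[float, float] = (0.021, 0.021)
    # image geometry
    n_rows: int = 232
    n_cols: int = 64
    center_row: float | None = None
    wall_thickness_px: float = 8.0
    # intensities (fraction of full scale)
    lumen_intensity: float = 0.08
    wall_intensity: float = 0.90
    tissue_intensity: float = 0.30
    # noise
    speckle_contrast: float = 0.5
    additive_sd: float = 0.02
    trace_noise_sd: float = 0.0  # mm, on the analytic waveform

    def __post_init__(self):
        if len(self.trough_times) != len(self.peak_times) + 1:
            raise ValueError("need one more trough than peaks")
        seq = np.ravel(list(zip(self.trough_times[:-1], self.peak_times)))
        seq = np.append(seq, self.trough_times[-1])
        if not np.all(np.diff(seq) > 0):
            raise ValueError("troughs and peaks must interleave and increase")
        c = self.cycle
        if min(c.tau_d, c.tau_r1, c.tau_r2) <= 0:
            raise ValueError("time constants must be positive")
        if self.frame_rate * min(c.tau_r1, c.tau_d) < 2:
            raise ValueError("frame rate too low to sample the fastest "
                             "timescale")
        if self.frame_rate <= 0 or self.duration <= 0:
            raise ValueError("frame_rate and duration must be positive")


@dataclass
class GroundTruth:
    """Analytic truth accompanying a simulated recording.

    Wall rows are sub-pixel floats in the raster coordinate frame (pixel
    ``r`` spans ``[r - 0.5, r + 0.5)``); diameters are mm.
    """

    t: np.ndarray                       # s, one entry per frame
    d: np.ndarray                       # mm, noiseless analytic diameter
    peak_times: tuple[float, ...]
    trough_times: tuple[float, ...]
    cycle_params: list[CycleParams]     # per cycle, after continuity solve
    y_t: np.ndarray | None = None       # rows, per (x, frame)
    y_b: np.ndarray | None = None
    center_row: float | None = None

    @property
    def cycle_boundaries(self) -> np.ndarray:
        return np.asarray(self.trough_times)


def _analytic_diameter(spec: PhantomSpec, t: np.ndarray):
    """Piecewise forward model, continuous at every window junction."""
    c = spec.cycle
    d = np.empty_like(t)
    params: list[CycleParams] = []
    d_end = c.a_d - c.b_d  # trough value entering the first cycle
    d[t < spec.trough_times[0]] = d_end
    for k, tp in enumerate(spec.peak_times):
        t0, t1 = spec.trough_times[k], spec.trough_times[k + 1]
        # dilatation: anchor the start at the previous segment's end value
        b_d = c.a_d - d_end
        m = (t >= t0) & (t < tp)
        d[m] = dilatation_model(t[m], c.a_d, b_d, t0, c.tau_d)
        d_peak = float(dilatation_model(tp, c.a_d, b_d, t0, c.tau_d))
        # relaxation: rescale both amplitudes jointly to hit the peak value
        s = (d_peak - c.a_r) / (c.b_r1 + c.b_r2)
        b1, b2 = s * c.b_r1, s * c.b_r2
        m = (t >= tp) & (t < t1)
        d[m] = relaxation_model(t[m], c.a_r, b1, b2, tp, c.tau_r1, c.tau_r2)
        d_end = float(relaxation_model(t1, c.a_r, b1, b2, tp,
                                       c.tau_r1, c.tau_r2))
        params.append(CycleParams(a_d=c.a_d, b_d=b_d, tau_d=c.tau_d,
                                  a_r=c.a_r, b_r1=b1, b_r2=b2,
                                  tau_r1=c.tau_r1, tau_r2=c.tau_r2))
    d[t >= spec.trough_times[-1]] = d_end
    return d, params


def simulate_diameter_trace(spec: PhantomSpec, seed: int | None = None):
    """Simulate one diameter waveform from the exponential forward model.

    Per cycle the diameter follows the single-exponential rise over the
    dilatation window and the bi-exponential decay over the relaxation
    window; amplitudes are re-solved at each junction so the waveform is
    continuous.  Gaussian noise of sd ``spec.trace_noise_sd`` (mm) is added
    when nonzero.  Returns ``(waveform, GroundTruth)``; the ground truth
    always carries the noiseless waveform.
    """
    n = int(round(spec.duration * spec.frame_rate))
    if n < 2:
        raise ValueError("duration too short")
    t = np.arange(n) / spec.frame_rate
    d, params = _analytic_diameter(spec, t)
    truth = GroundTruth(t=t, d=d.copy(), peak_times=spec.peak_times,
                        trough_times=spec.trough_times, cycle_params=params)
    if spec.trace_noise_sd > 0:
        rng = np.random.default_rng(seed)
        d = d + rng.normal(0.0, spec.trace_noise_sd, size=d.shape)
    return d, truth


def rayleigh_speckle(shape, contrast: float, rng: np.random.Generator):
    """Unit-mean multiplicative speckle field.

    A Rayleigh-distributed envelope (the first-order amplitude statistics of
    fully developed speckle) normalised to mean 1, blended with a constant 1
    by ``contrast``: the result is ``(1 - contrast) + contrast * R / E[R]``.
    """
    if not 0 <= contrast <= 1:
        raise ValueError("contrast must be in [0, 1]")
    r = rng.rayleigh(scale=1.0, size=shape)
    r /= np.sqrt(np.pi / 2.0)  # Rayleigh(1) mean
    return (1.0 - contrast) + contrast * r


def _band_coverage(rows: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fraction of each pixel (centred on integer row) covered by [lo, hi]."""
    return np.clip(np.minimum(hi, rows + 0.5) - np.maximum(lo, rows - 0.5),
                   0.0, 1.0)


def simulate_cine(spec: PhantomSpec, seed: int | None = None):
    """Rasterise a pulsating two-wall vessel into a speckled cine loop.

    Frames hold a dark lumen band between two bright wall bands whose
    sub-pixel edge positions follow the forward-model waveform; tissue
    fills the rest.  Echogenic regions (walls and tissue) carry
    multiplicative Rayleigh speckle; the whole frame gets additive Gaussian
    noise.  Frames are quantised to uint16 so loops round-trip bit-exactly
    through DICOM.  Returns ``(CineLoop, GroundTruth)``.
    """
    d_mm, truth = simulate_diameter_trace(spec, seed=None)  # noiseless walls
    ax_sp = spec.pixel_spacing[0]
    center = spec.center_row if spec.center_row is not None \
        else (spec.n_rows - 1) / 2.0
    half_px = d_mm / (2.0 * ax_sp)
    y_t = center - half_px                  # top lumen edge, per frame
    y_b = center + half_px
    th = spec.wall_thickness_px
    if np.min(y_t - th) < 1 or np.max(y_b + th) > spec.n_rows - 2:
        raise ValueError("vessel exceeds the frame; enlarge n_rows")

    rng = np.random.default_rng(seed)
    rows = np.arange(spec.n_rows, dtype=float)
    n = len(d_mm)
    frames = np.empty((n, spec.n_rows, spec.n_cols), dtype=np.uint16)
    for j in range(n):
        cov_wt = _band_coverage(rows, y_t[j] - th, y_t[j])
        cov_wb = _band_coverage(rows, y_b[j], y_b[j] + th)
        cov_lum = _band_coverage(rows, y_t[j], y_b[j])
        cov_tis = 1.0 - cov_wt - cov_wb - cov_lum
        profile_echo = spec.wall_intensity * (cov_wt + cov_wb) \
            + spec.tissue_intensity * cov_tis
        profile_lum = spec.lumen_intensity * cov_lum
        echo = np.repeat(profile_echo[:, None], spec.n_cols, axis=1)
        lum = np.repeat(profile_lum[:, None], spec.n_cols, axis=1)
        img = echo * rayleigh_speckle(echo.shape, spec.speckle_contrast, rng) \
            + lum
        if spec.additive_sd > 0:
            img = img + rng.normal(0.0, spec.additive_sd, size=img.shape)
        frames[j] = np.round(np.clip(img, 0.0, 1.0) * 60000.0).astype(np.uint16)

    truth.y_t = np.repeat(y_t[None, :], spec.n_cols, axis=0)
    truth.y_b = np.repeat(y_b[None, :], spec.n_cols, axis=0)
    truth.center_row = center
    loop = CineLoop(frames=frames, pixel_spacing=spec.pixel_spacing,
                    frame_interval=1.0 / spec.frame_rate,
                    source_id=f"phantom-seed{seed}")
    return loop, truth


def inject_lumen_artefact(loop: CineLoop, truth: GroundTruth,
                          intensity: float = 0.7,
                          thickness_px: int = 6) -> CineLoop:
    """Overlay a bright horizontal band inside the lumen of every frame.

    Emulates a slice-thickness artefact — out-of-plane echoes appearing as
    a dense band within the vessel — the most common cause of unusable
    recordings.  Returns a new loop; the input is untouched.
    """
    frames = loop.frames.copy()
    center = int(round(truth.center_row))
    lo, hi = center - thickness_px // 2, center + (thickness_px + 1) // 2
    level = np.uint16(round(intensity * 60000))
    frames[:, lo:hi, :] = np.maximum(frames[:, lo:hi, :], level)
    return CineLoop(frames=frames, pixel_spacing=loop.pixel_spacing,
                    frame_interval=loop.frame_interval,
                    source_id=loop.source_id + "+artefact")


# --------------------------------------------------------------------------
# Recovery experiments
# --------------------------------------------------------------------------

#: Parameter ranges a relaxation window of a brachial recording plausibly
#: spans (mm, s); used by :func:`recovery_experiment`.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "a_r": (2.8, 3.2),
    "b_r1": (0.3, 0.6),
    "b_r2": (0.2, 0.4),
    "tau_r1": (0.05, 0.12),
    "tau_r2": (0.6, 1.4),
}


def recovery_experiment(n_replicates: int = 100,
                        ranges: dict[str, tuple[float, float]] | None = None,
                        noise_ladder: tuple[float, ...] = (0.0, 0.5, 1.0),
                        seed: int = 0,
                        window_duration: float = 1.2,
                        sample_rate: float = 50.0,
                        settings=None):
    """Measure how well the fitter recovers known relaxation constants.

    For each noise level (Gaussian sd in *pixels*, one pixel = the
    ``settings.pixel_size``) and each replicate: draw true parameters
    uniformly from ``ranges``, synthesise a relaxation window, fit it with
    the default initialisation, and record the relative errors of both time
    constants.  Returns a dict with the raw per-fit table (``"fits"``, a
    pandas DataFrame) and per-level aggregates (``"summary"``): bias and
    median absolute relative error of T_R1/T_R2, and the fraction of fits
    accepted.
    """
    import pandas as pd

    from .fitting import FitSettings, accept_fit, fit_relaxation

    if settings is None:
        settings = FitSettings()
    ranges = dict(DEFAULT_RANGES, **(ranges or {}))
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(window_duration * sample_rate))) / sample_rate
    rows = []
    for level in noise_ladder:
        sd_mm = level * settings.pixel_size
        for rep in range(n_replicates):
            p = {k: rng.uniform(*ranges[k]) for k in ranges}
            clean = relaxation_model(t, p["a_r"], p["b_r1"], p["b_r2"],
                                     0.0, p["tau_r1"], p["tau_r2"])
            noisy = clean + rng.normal(0.0, sd_mm, size=clean.shape) \
                if sd_mm > 0 else clean
            fit = accept_fit(fit_relaxation(noisy, t, settings=settings),
                             settings)
            rows.append({
                "noise_px": level, "replicate": rep,
                "tau2_true": p["tau_r2"], "tau2_fit": fit.tau2,
                "tau1_true": p["tau_r1"], "tau1_fit": fit.tau1,
                "rel_err_tau2": (fit.tau2 - p["tau_r2"]) / p["tau_r2"],
                "rel_err_tau1": (fit.tau1 - p["tau_r1"]) / p["tau_r1"],
                "rmse": fit.rmse, "accepted": fit.accepted,
            })
    fits = pd.DataFrame(rows)
    summary = fits.groupby("noise_px").agg(
        bias_tau2=("rel_err_tau2", "mean"),
        med_abs_rel_err_tau2=("rel_err_tau2", lambda s: s.abs().median()),
        med_abs_rel_err_tau1=("rel_err_tau1", lambda s: s.abs().median()),
        accepted_fraction=("accepted", "mean"),
    ).reset_index()
    return {"fits": fits, "summary": summary}


def wall_error_experiment(n_seeds: int = 20, spec: PhantomSpec | None = None,
                          config=None, seed0: int = 1):
    """Segment seeded phantom loops and score wall localisation in microns.

    For each seed, simulate a cine loop, run the level-set segmentation and
    wall-trace extraction with default settings, and compute the mean
    absolute difference between detected and true wall rows (both walls,
    all valid cells), converted to microns via the axial pixel spacing.
    Returns ``(per_seed_errors_um, details)``.
    """
    from .cine_io import RoiRect
    from .segmentation import (LevelSetConfig, extract_wall_traces,
                               segment_lumen)

    if spec is None:
        spec = PhantomSpec(peak_times=(0.5, 1.5),
                           trough_times=(0.2, 1.2, 1.95),
                           frame_rate=30.0, duration=2.0)
    if config is None:
        config = LevelSetConfig()
    ax_um = spec.pixel_spacing[0] * 1000.0
    errors, details = [], []
    for i in range(n_seeds):
        seed = seed0 + i
        loop, truth = simulate_cine(spec, seed=seed)
        roi = _default_roi(spec, truth)
        contours = segment_lumen(loop, roi, config)
        traces = extract_wall_traces(contours, roi, loop, config)
        cols = traces.x_px.astype(int)
        err_t = np.abs(traces.y_t - truth.y_t[cols, :])
        err_b = np.abs(traces.y_b - truth.y_b[cols, :])
        err = np.concatenate([err_t[traces.qc_mask], err_b[traces.qc_mask]])
        if err.size == 0:
            raise RuntimeError(f"segmentation produced no valid cells "
                               f"(seed {seed})")
        errors.append(float(np.mean(err)) * ax_um)
        details.append({"seed": seed, "n_cells": int(err.size),
                        "mean_err_um": errors[-1]})
    return np.asarray(errors), details


def _default_roi(spec: PhantomSpec, truth: GroundTruth):
    """A seed rectangle inside the lumen with a margin from both walls."""
    from .cine_io import RoiRect

    margin = 12
    top = int(np.ceil(np.max(truth.y_t))) + margin
    bot = int(np.floor(np.min(truth.y_b))) - margin
    c0 = spec.n_cols // 8
    return RoiRect(row_min=top, row_max=bot,
                   col_min=c0, col_max=spec.n_cols - c0)
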