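"""Lumen wall localisation by edge-stopping level-set evolution.

A user places a rectangle inside the lumen in the first frame.  From its
boundary a morphological geodesic active contour — a level-set evolution
whose edge-indicator is an inverse Gaussian gradient of the frame — is
ballooned *outwards* until the brightness contrast of the wall stops it, so
the converged zero level set lies on the lumen-wall interface outside the
seed rectangle.  Subsequent frames warm-start from the previous frame's
converged region (eroded to accommodate inward wall motion); a flag forces
independent re-initialisation for ablation.

The converged contour of each frame is reduced to single-valued anterior
(top) and posterior (bottom) wall traces on the lateral grid of the seed
rectangle.  Where a contour is "S"- or "Z"-shaped and yields several row
values at one column, their arithmetic mean is used.  An optional
sub-pixel refinement then relocates each wall sample to the axial
intensity-gradient extremum nearest the level-set estimate, which brings
the localisation error down to a fraction of a voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import find_contours
from skimage.segmentation import (inverse_gaussian_gradient,
                                  morphological_geodesic_active_contour)

from .cine_io import CineLoop, RoiRect

__all__ = [
    "LevelSetConfig", "FrameContour", "ContourSet", "WallTraces",
    "QcThresholds", "QcVerdict", "segment_lumen", "extract_wall_traces",
    "qc_recording",
]


@dataclass(frozen=True)
class LevelSetConfig:
    """Every constant of the level-set stage, in one place.

    sigma : Gaussian scale (px) of the edge indicator.
    alpha : steepness of the inverse-gradient edge indicator; larger values
        drive the indicator closer to zero at a given edge strength.
    threshold : balloon force acts only where the edge indicator exceeds
        this, so the front stops in the low-indicator trough of a wall edge.
    smoothing : morphological smoothing passes per iteration (curvature-like
        regularisation).
    balloon : +1 expands outward from the interior seed (the only mode the
        pipeline uses; -1 would shrink).
    max_iter / block / stable_blocks / residual_frac : the evolution runs
        in blocks of ``block`` iterations and is converged once the number
        of pixels changing per block stays at or below ``residual_frac`` of
        the region area for ``stable_blocks`` consecutive blocks (the
        morphological front keeps flickering by a few boundary pixels even
        at equilibrium); ``max_iter`` caps the total before the frame is
        flagged failed.
    warm_start : initialise each frame from the previous frame's converged
        region, eroded by ``erosion_px`` so inward wall motion between
        frames stays reachable; when False every frame restarts from the
        seed rectangle.
    lateral_margin : columns kept either side of the seed rectangle when
        cropping the evolution domain (lateral image borders are open:
        contour contact there is expected and harmless, unlike top/bottom
        contact which flags failure).
    subpixel_refine : relocate wall samples to the parabolic peak of the
        smoothed axial intensity gradient within ``refine_halfwidth`` px of
        the level-set estimate; ``refine_sigma`` = (axial, lateral)
        Gaussian smoothing of the frame used for refinement only.
    """

    sigma: float = 2.0
    alpha: float = 1000.0
    threshold: float = 0.5
    smoothing: int = 1
    balloon: int = 1
    max_iter: int = 400
    block: int = 10
    stable_blocks: int = 2
    residual_frac: float = 0.005
    warm_start: bool = True
    erosion_px: int = 7
    lateral_margin: int = 6
    subpixel_refine: bool = True
    refine_halfwidth: int = 5
    refine_sigma: tuple[float, float] = (1.0, 2.0)

    def __post_init__(self):
        if not (self.sigma > 0 and self.alpha > 0 and 0 < self.threshold < 1
                and self.max_iter > 0 and self.block > 0
                and self.erosion_px >= 0 and self.lateral_margin >= 0
                and self.refine_halfwidth >= 2):
            raise ValueError("LevelSetConfig values out of documented range")
        if self.balloon not in (1, -1):
            raise ValueError("balloon must be +1 (outward) or -1")


@dataclass
class FrameContour:
    """Converged zero-level contour of one frame, with diagnostics.

    ``points`` is an (N, 2) float array of (row, col) positions in full-frame
    pixel coordinates.
    """

    points: np.ndarray
    iterations: int
    residual: float          # changed pixels in the final block
    failed: bool = False
    reason: str = ""


@dataclass
class ContourSet:
    """Per-frame contours plus the evolution's lateral crop window."""

    frames: list[FrameContour]
    col_offset: int
    col_stop: int

    @property
    def n_failed(self) -> int:
        return sum(f.failed for f in self.frames)


@dataclass
class WallTraces:
    """Single-valued top/bottom wall rows on a common lateral grid.

    ``y_t``/``y_b`` are (n_x, n_frames) row positions in px (full-frame
    coordinates); ``qc_mask`` is True where both walls are valid (and
    ``y_t < y_b``).  ``x_mm`` converts the lateral grid via pixel spacing.
    """

    x_px: np.ndarray
    x_mm: np.ndarray
    y_t: np.ndarray
    y_b: np.ndarray
    qc_mask: np.ndarray
    pixel_spacing: tuple[float, float]
    frame_interval: float

    @property
    def n_frames(self) -> int:
        return int(self.y_t.shape[1])

    @property
    def valid_fraction(self) -> float:
        return float(np.mean(self.qc_mask))


def _normalized(frame: np.ndarray) -> np.ndarray:
    f = frame.astype(float)
    peak = f.max()
    return f / peak if peak > 0 else f


def _evolve(gimage: np.ndarray, init: np.ndarray, config: LevelSetConfig):
    """Run the morphological GAC in blocks until the region is stable."""
    u = init.astype(np.uint8)
    iters = 0
    stable = 0
    residual = np.inf
    while iters < config.max_iter:
        nxt = morphological_geodesic_active_contour(
            gimage, num_iter=config.block, init_level_set=u,
            smoothing=config.smoothing, threshold=config.threshold,
            balloon=config.balloon,
        ).astype(np.uint8)
        iters += config.block
        residual = int(np.sum(nxt != u))
        u = nxt
        tol = config.residual_frac * max(int(u.sum()), 1)
        if residual <= tol:
            stable += 1
            if stable >= config.stable_blocks:
                return u, iters, residual, True
        else:
            stable = 0
    return u, iters, residual, False


def segment_lumen(cine: CineLoop, roi: RoiRect,
                  config: LevelSetConfig = LevelSetConfig()) -> ContourSet:
    """Locate the lumen boundary in every frame of a cine loop.

    The evolution domain is the full axial extent of the frame, cropped
    laterally to the seed rectangle plus ``config.lateral_margin`` columns.
    A frame is flagged failed (never silently returned) when the evolution
    does not converge within the iteration budget, when the region reaches
    the top or bottom image border (no wall edge stopped it), or when the
    converged contour does not surround the seed rectangle.

    The result is deterministic: repeated runs on the same inputs are
    bit-identical.
    """
    roi.validate_inside(cine.frame_shape)
    rows, cols = cine.frame_shape
    c0 = max(roi.col_min - config.lateral_margin, 0)
    c1 = min(roi.col_max + config.lateral_margin, cols)

    seed = np.zeros((rows, c1 - c0), dtype=np.uint8)
    seed[roi.row_min:roi.row_max, roi.col_min - c0:roi.col_max - c0] = 1

    prev = None
    out: list[FrameContour] = []
    for j in range(cine.n_frames):
        frame = _normalized(cine.frames[j][:, c0:c1])
        gimage = inverse_gaussian_gradient(frame, alpha=config.alpha,
                                           sigma=config.sigma)
        if prev is not None and config.warm_start:
            init = ndimage.binary_erosion(
                prev, iterations=config.erosion_px).astype(np.uint8)
            init |= seed  # never lose the seed region
        else:
            init = seed
        u, iters, residual, converged = _evolve(gimage, init, config)

        failed, reason = False, ""
        if not converged:
            failed, reason = True, "no convergence within iteration budget"
        elif u[0, :].any() or u[-1, :].any():
            failed, reason = True, "evolution reached image border"
        else:
            interior = u[roi.row_min:roi.row_max,
                         roi.col_min - c0:roi.col_max - c0]
            if not interior.all():
                failed, reason = True, "contour does not enclose seed"
        pts = np.empty((0, 2))
        if not failed:
            segs = find_contours(u.astype(float), 0.5)
            if segs:
                pts = np.vstack(segs)
                pts[:, 1] += c0  # back to full-frame columns
            mid = roi.mid_row
            has_top = np.any(pts[:, 0] < roi.row_min) if pts.size else False
            has_bot = np.any(pts[:, 0] >= roi.row_max) if pts.size else False
            if not (has_top and has_bot):
                failed, reason = True, "missing wall contour on one side"
        out.append(FrameContour(points=pts, iterations=iters,
                                residual=float(residual),
                                failed=failed, reason=reason))
        prev = u if not failed else None
    return ContourSet(frames=out, col_offset=c0, col_stop=c1)


def _valid_wall_mask(y_t: np.ndarray, y_b: np.ndarray) -> np.ndarray:
    """Cells are valid only where both walls exist and the top wall is
    above the bottom wall.  The midline split makes inversion impossible
    for raw contour averages, but sub-pixel refinement can in principle
    cross the walls near artefacts; such cells are masked individually."""
    return np.isfinite(y_t) & np.isfinite(y_b) & (y_t < y_b)


def _refine_wall(frame_sm_grad: np.ndarray, col: int, y0: float,
                 sign: int, halfwidth: int) -> float:
    """Sub-pixel wall row: parabolic peak of the signed axial gradient."""
    n = frame_sm_grad.shape[0]
    i0 = int(round(y0))
    lo, hi = max(i0 - halfwidth, 1), min(i0 + halfwidth + 1, n - 1)
    if hi - lo < 3:
        return y0
    g = sign * frame_sm_grad[lo:hi, col]
    i = int(np.argmax(g))
    if i == 0 or i == len(g) - 1:
        return y0
    denom = g[i - 1] - 2.0 * g[i] + g[i + 1]
    if denom >= 0:
        return float(lo + i)
    return float(lo + i + 0.5 * (g[i - 1] - g[i + 1]) / denom)


def extract_wall_traces(contours: ContourSet, roi: RoiRect, cine: CineLoop,
                        config: LevelSetConfig = LevelSetConfig()
                        ) -> WallTraces:
    """Reduce per-frame contours to single-valued top/bottom wall traces.

    Contour points are split into a top and a bottom group by the vertical
    midline of the seed rectangle.  At each column of the rectangle's
    lateral grid, multiple row values within one group (from "S"/"Z" shaped
    contours) are averaged; columns with no point in a group are QC-masked,
    as is any cell where the averaged top row does not lie above the
    averaged bottom row.  Failed frames are masked entirely.
    """
    if all(f.failed for f in contours.frames):
        pass  # fully masked traces are still a valid (if useless) result
    grid = np.arange(roi.col_min, roi.col_max)
    nx, nt = len(grid), len(contours.frames)
    y_t = np.full((nx, nt), np.nan)
    y_b = np.full((nx, nt), np.nan)
    ax_sp, lat_sp = cine.pixel_spacing
    mid = roi.mid_row

    for j, fc in enumerate(contours.frames):
        if fc.failed or fc.points.size == 0:
            continue
        pts = fc.points
        cols = np.round(pts[:, 1]).astype(int)
        inside = (cols >= roi.col_min) & (cols < roi.col_max)
        pts, cols = pts[inside], cols[inside]
        top = pts[:, 0] < mid
        idx = cols - roi.col_min
        for sel, target in ((top, y_t), (~top, y_b)):
            if not sel.any():
                continue
            sums = np.bincount(idx[sel], weights=pts[sel, 0], minlength=nx)
            cnts = np.bincount(idx[sel], minlength=nx)
            with np.errstate(invalid="ignore"):
                target[:, j] = np.where(cnts > 0, sums / np.maximum(cnts, 1),
                                        np.nan)

        if config.subpixel_refine:
            frame = _normalized(cine.frames[j])
            sm = ndimage.gaussian_filter(frame, sigma=config.refine_sigma)
            grad = np.gradient(sm, axis=0)
            for i, c in enumerate(grid):
                if np.isfinite(y_t[i, j]):
                    y_t[i, j] = _refine_wall(grad, c, y_t[i, j], -1,
                                             config.refine_halfwidth)
                if np.isfinite(y_b[i, j]):
                    y_b[i, j] = _refine_wall(grad, c, y_b[i, j], +1,
                                             config.refine_halfwidth)

    qc = _valid_wall_mask(y_t, y_b)
    y_t[~qc] = np.nan
    y_b[~qc] = np.nan
    return WallTraces(x_px=grid.astype(float), x_mm=grid * lat_sp,
                      y_t=y_t, y_b=y_b, qc_mask=qc,
                      pixel_spacing=cine.pixel_spacing,
                      frame_interval=cine.frame_interval)


# --------------------------------------------------------------------------
# Recording-level quality control
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class QcThresholds:
    """Exclusion thresholds for a whole recording.

    mask_fraction : exclude when more than this fraction of (x, t) cells is
        QC-masked.
    jump_px : exclude when the median (over columns) frame-to-frame wall
        displacement exceeds this anywhere — wall traces should be
        continuous in time.
    artefact_level : exclude when the mean intensity inside the detected
        lumen exceeds this fraction of the frame's bright reference (99th
        percentile) — the proxy for a slice-thickness artefact filling the
        lumen with spurious echoes.
    """

    mask_fraction: float = 0.5
    jump_px: float = 5.0
    artefact_level: float = 0.35

    def __post_init__(self):
        if not (0 < self.mask_fraction <= 1 and self.jump_px > 0
                and 0 < self.artefact_level < 1):
            raise ValueError("QcThresholds out of range")


@dataclass
class QcVerdict:
    usable: bool
    reasons: tuple[str, ...]
    metrics: dict


def qc_recording(traces: WallTraces,
                 thresholds: QcThresholds = QcThresholds(),
                 cine: CineLoop | None = None) -> QcVerdict:
    """Decide whether a recording is usable; always returns a verdict.

    The intraluminal-artefact check needs the original frames; it is
    skipped when ``cine`` is not given.
    """
    reasons: list[str] = []
    metrics: dict = {}

    masked = 1.0 - traces.valid_fraction
    metrics["masked_fraction"] = masked
    if masked > thresholds.mask_fraction:
        reasons.append("insufficient valid wall samples")

    jumps = []
    for y in (traces.y_t, traces.y_b):
        dy = np.abs(np.diff(y, axis=1))
        ok = np.isfinite(dy).any(axis=0)  # frame pairs with any valid column
        if ok.any():
            # per frame-pair, median over columns
            med = np.nanmedian(dy[:, ok], axis=0)
            jumps.append(np.nanmax(med))
    if jumps:
        metrics["max_frame_jump_px"] = float(max(jumps))
        if max(jumps) > thresholds.jump_px:
            reasons.append("discontinuous wall trace")

    if cine is not None and traces.qc_mask.any():
        lum_vals = []
        ref = []
        margin = 3
        for j in range(traces.n_frames):
            valid = traces.qc_mask[:, j]
            if not valid.any():
                continue
            frame = _normalized(cine.frames[j])
            ref.append(np.percentile(frame, 99))
            for i in np.flatnonzero(valid):
                top = int(np.ceil(traces.y_t[i, j])) + margin
                bot = int(np.floor(traces.y_b[i, j])) - margin
                if bot > top:
                    lum_vals.append(frame[top:bot, int(traces.x_px[i])].mean())
        if lum_vals and ref:
            level = float(np.mean(lum_vals) / np.mean(ref))
            metrics["lumen_intensity_ratio"] = level
            if level > thresholds.artefact_level:
                reasons.append("intraluminal artefact")

    return QcVerdict(usable=not reasons, reasons=tuple(reasons),
                     metrics=metrics)
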