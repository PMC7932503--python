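"""From wall traces to the diameter surface D(x, t) and cardiac-cycle windows.

The diameter at each lateral position is simply the absolute distance
between the two wall rows, D = |y_b - y_t|, converted to millimetres by the
axial pixel spacing.  Each cross-section's waveform is then partitioned
into a systolic dilatation window (trough -> peak) and a diastolic
relaxation window (peak -> next trough) per cardiac cycle.  Extrema are
found automatically by prominence-based peak detection on a lightly
smoothed copy of the waveform (the fit itself always runs on the raw
samples); a manual annotation mapping can override detection entirely,
reproducing a hand-marked workflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .segmentation import WallTraces

__all__ = ["DiameterMap", "CycleWindow", "CycleSettings",
           "compute_diameter", "detect_cycles", "detect_cycles_map"]


@dataclass
class DiameterMap:
    """Diameter surface D(x, t) in mm; QC-masked cells are NaN."""

    x_px: np.ndarray
    x_mm: np.ndarray
    d: np.ndarray                 # (n_x, n_frames), mm
    pixel_spacing: tuple[float, float]
    frame_interval: float

    @property
    def n_frames(self) -> int:
        return int(self.d.shape[1])

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def qc_mask(self) -> np.ndarray:
        return np.isfinite(self.d)


@dataclass(frozen=True)
class CycleWindow:
    """One cardiac cycle at one cross-section, as sample indices.

    The dilatation window is ``[trough, peak]`` and the relaxation window
    ``[peak, next_trough]``; they share the peak sample, so the partition
    of the cycle is exhaustive and non-overlapping.
    """

    trough: int
    peak: int
    next_trough: int

    def __post_init__(self):
        if not self.trough < self.peak < self.next_trough:
            raise ValueError("window indices must satisfy "
                             "trough < peak < next_trough")
        if self.peak - self.trough + 1 < 4 \
                or self.next_trough - self.peak + 1 < 4:
            raise ValueError("each window needs at least 4 samples")


@dataclass(frozen=True)
class CycleSettings:
    """Extremum-detection configuration.

    smooth_window : moving-average length (samples) of the detection copy;
        1 disables smoothing.  Smoothing is used for detection only.
    prominence_fraction : required peak prominence as a fraction of the
        waveform's 5th-95th percentile span (robust pulse amplitude).
    min_window_samples : windows shorter than this are dropped.
    """

    smooth_window: int = 5
    prominence_fraction: float = 0.25
    min_window_samples: int = 4

    def __post_init__(self):
        if self.smooth_window < 1 or not 0 < self.prominence_fraction < 1 \
                or self.min_window_samples < 4:
            raise ValueError("CycleSettings out of range")


def compute_diameter(traces: WallTraces) -> DiameterMap:
    """D(x, t) = |y_b - y_t| x axial spacing; masked cells propagate as NaN."""
    ax_sp = traces.pixel_spacing[0]
    d = np.abs(traces.y_b - traces.y_t) * ax_sp
    d = np.where(traces.qc_mask, d, np.nan)
    return DiameterMap(x_px=traces.x_px.copy(), x_mm=traces.x_mm.copy(),
                       d=d, pixel_spacing=traces.pixel_spacing,
                       frame_interval=traces.frame_interval)


def detect_cycles(d: np.ndarray, t: np.ndarray,
                  settings: CycleSettings = CycleSettings(),
                  annotations: list[tuple[int, int, int]] | None = None
                  ) -> list[CycleWindow]:
    """Partition one diameter waveform into cardiac-cycle windows.

    Peaks (systole) and troughs are located by prominence-based extremum
    detection on a moving-average-smoothed copy; windows are built
    trough -> peak -> trough and incomplete leading/trailing partial cycles
    are dropped.  ``annotations`` — a list of (trough, peak, next_trough)
    sample indices — overrides detection entirely.  Returns an empty list
    when no full cycle is detectable (e.g. a constant waveform).
    """
    if annotations is not None:
        return [CycleWindow(*w) for w in annotations]
    d = np.asarray(d, dtype=float)
    t = np.asarray(t, dtype=float)
    if d.ndim != 1 or d.shape != t.shape:
        raise ValueError("d and t must be matching 1-D arrays")
    finite = np.isfinite(d)
    if finite.sum() < 2 * settings.min_window_samples:
        return []
    work = d.copy()
    if not finite.all():  # interpolate gaps for detection only
        work[~finite] = np.interp(t[~finite], t[finite], d[finite])
    if settings.smooth_window > 1:
        work = uniform_filter1d(work, size=settings.smooth_window,
                                mode="nearest")
    span = np.percentile(work, 95) - np.percentile(work, 5)
    if span <= 0:
        return []
    prom = settings.prominence_fraction * span
    peaks, _ = find_peaks(work, prominence=prom)
    if peaks.size == 0:
        return []
    # Smoothing shifts extrema by a sample or two on asymmetric pulses, so
    # each detected peak is snapped to the raw-waveform maximum within one
    # smoothing window of it.
    w = settings.smooth_window
    raw = np.where(finite, d, work)
    snapped = []
    for p in peaks:
        lo = max(p - w, 0)
        snapped.append(int(lo + np.argmax(raw[lo:min(p + w + 1, len(raw))])))
    peaks = np.unique(snapped)
    # Troughs are the raw minima between consecutive peaks.  Before the
    # first peak the *last* minimum is taken and after the last peak the
    # *first*, so flat diastolic plateaus at the recording edges resolve to
    # the sample adjacent to the cycle; cycles cut off by the recording
    # edge (no descent back to a minimum) fail the window-length check and
    # drop.
    troughs = []
    seg = raw[: peaks[0] + 1]
    troughs.append(int(len(seg) - 1 - np.argmin(seg[::-1])))
    for a, b in zip(peaks[:-1], peaks[1:]):
        troughs.append(int(a + np.argmin(raw[a:b + 1])))
    troughs.append(int(peaks[-1] + np.argmin(raw[peaks[-1]:])))

    windows: list[CycleWindow] = []
    for k, p in enumerate(peaks):
        w0, w1 = troughs[k], troughs[k + 1]
        if not (w0 < p < w1):
            continue
        if p - w0 + 1 < settings.min_window_samples \
                or w1 - p + 1 < settings.min_window_samples:
            continue
        windows.append(CycleWindow(trough=w0, peak=int(p), next_trough=w1))
    return windows


def detect_cycles_map(dmap: DiameterMap,
                      settings: CycleSettings = CycleSettings(),
                      stride: int = 1,
                      annotations: dict[int, list] | None = None
                      ) -> dict[int, list[CycleWindow]]:
    """Detect cycles at every (strided) cross-section of a diameter map.

    Returns ``{x_index: [CycleWindow, ...]}``; cross-sections with no
    detectable cycle are omitted.  ``annotations`` maps x indices to manual
    window lists and overrides detection at those cross-sections.
    """
    t = dmap.t
    out: dict[int, list[CycleWindow]] = {}
    for ix in range(0, dmap.d.shape[0], stride):
        ann = annotations.get(ix) if annotations else None
        wins = detect_cycles(dmap.d[ix], t, settings, annotations=ann)
        if wins:
            out[ix] = wins
    return out
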