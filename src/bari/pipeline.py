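"""End-to-end convenience: cine loop -> BARI."""

from __future__ import annotations

from dataclasses import dataclass

from .cine_io import CineLoop, RoiRect
from .cohort import BariResult, compute_bari
from .fitting import FitSettings, fit_diameter_map
from .segmentation import (LevelSetConfig, QcThresholds, QcVerdict,
                           extract_wall_traces, qc_recording, segment_lumen)
from .wall_dynamics import CycleSettings, compute_diameter, detect_cycles_map


@dataclass
class LoopAnalysis:
    """Everything the single-recording pipeline produced."""

    traces: object
    qc: QcVerdict
    dmap: object
    fits: list
    result: BariResult


def analyse_loop(cine: CineLoop, roi: RoiRect,
                 ls_config: LevelSetConfig = LevelSetConfig(),
                 cycle_settings: CycleSettings = CycleSettings(),
                 fit_settings: FitSettings | None = None,
                 qc_thresholds: QcThresholds = QcThresholds(),
                 stride: int = 1) -> LoopAnalysis:
    """Run segmentation -> traces -> QC -> diameters -> cycles -> fits -> BARI.

    When the recording fails QC the result carries a missing BARI with the
    QC reasons; nothing is fitted.  ``stride`` subsamples cross-sections
    for speed.  ``fit_settings`` defaults to :class:`FitSettings` with the
    loop's axial pixel spacing as the pixel size.
    """
    if fit_settings is None:
        fit_settings = FitSettings(pixel_size=cine.pixel_spacing[0])
    contours = segment_lumen(cine, roi, ls_config)
    traces = extract_wall_traces(contours, roi, cine, ls_config)
    qc = qc_recording(traces, qc_thresholds, cine=cine)
    dmap = compute_diameter(traces)
    if not qc.usable:
        result = BariResult(bari=None, n_accepted=0,
                            reason="recording excluded: "
                                   + "; ".join(qc.reasons))
        return LoopAnalysis(traces=traces, qc=qc, dmap=dmap, fits=[],
                            result=result)
    windows = detect_cycles_map(dmap, cycle_settings, stride=stride)
    fits = fit_diameter_map(dmap, windows, fit_settings)
    result = compute_bari(fits)
    return LoopAnalysis(traces=traces, qc=qc, dmap=dmap, fits=fits,
                        result=result)
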