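"""Reading and writing cine loops, wall traces, diameter maps and cohort tables.

Every downstream stage consumes only the in-memory containers defined here:
:class:`CineLoop` (the multi-frame grayscale recording with its physical
calibration), :class:`RoiRect` (the user-placed seed rectangle inside the
lumen) and :class:`ParticipantRecord` (one row of the cohort table).

Coordinate convention: row index = axial depth *y*, increasing downward as
on a B-mode display; column index = lateral position *x*.  Contours and
diameters are stored in millimetres (pixels x spacing), time in seconds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd


class CineFormatError(ValueError):
    """Raised when a cine file cannot be interpreted as a multi-frame loop."""


class CineMetadataError(ValueError):
    """Raised when mandatory calibration metadata (spacing/timing) is absent."""


class CohortTableError(ValueError):
    """Raised for malformed cohort tables."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RoiRect:
    """Half-open pixel rectangle ``[row_min, row_max) x [col_min, col_max)``.

    The rectangle seeds the level-set evolution and must lie wholly within
    the lumen, with a margin from both walls so that wall motion over the
    cardiac cycle never crosses it.
    """

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self) -> None:
        if not (self.row_min < self.row_max and self.col_min < self.col_max):
            raise ValueError("RoiRect must be nonempty")
        if self.row_min < 0 or self.col_min < 0:
            raise ValueError("RoiRect indices must be non-negative")

    @property
    def mid_row(self) -> float:
        """Vertical midline separating anterior from posterior wall points."""
        return 0.5 * (self.row_min + self.row_max - 1)

    def validate_inside(self, shape: tuple[int, int]) -> None:
        rows, cols = shape
        if self.row_min <= 0 or self.col_min <= 0 \
                or self.row_max >= rows or self.col_max >= cols:
            raise ValueError(
                f"RoiRect {self} must be strictly inside a {rows}x{cols} frame"
            )


@dataclass
class CineLoop:
    """A multi-frame grayscale recording with physical calibration.

    Parameters
    ----------
    frames
        3-D intensity array, ``(frame, row, column)``; all values finite.
    pixel_spacing
        ``(axial mm/px, lateral mm/px)``; both strictly positive.
    frame_interval
        Seconds between consecutive frames; strictly positive.
    source_id
        Opaque identifier carried through for provenance.
    """

    frames: np.ndarray
    pixel_spacing: tuple[float, float]
    frame_interval: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (frame, row, column)")
        if self.frames.shape[0] < 2:
            raise CineFormatError("a cine loop needs at least 2 frames")
        if not np.all(np.isfinite(self.frames.astype(float, copy=False))):
            raise ValueError("frames must be finite")
        ax, lat = self.pixel_spacing
        if not (ax > 0 and lat > 0):
            raise ValueError("pixel_spacing components must be > 0")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        self.pixel_spacing = (float(ax), float(lat))
        self.frame_interval = float(self.frame_interval)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval


_GROUPS = ("HV", "small", "moderate", "large")


def group_from_apd(apd_mm: float | None) -> str:
    """Aneurysm size group from the anteroposterior diameter (mm).

    ``small`` is 30-39 mm, ``moderate`` 40-55 mm (both ends included),
    ``large`` strictly above 55 mm.  Sub-aneurysmal diameters (< 30 mm) and
    absent measurements map to ``HV`` (no aneurysm).
    """
    if apd_mm is None or (isinstance(apd_mm, float) and math.isnan(apd_mm)):
        return "HV"
    if apd_mm <= 0:
        raise ValueError("APD must be positive")
    if apd_mm < 30:
        return "HV"
    if apd_mm < 40:
        return "small"
    if apd_mm <= 55:
        return "moderate"
    return "large"


@dataclass
class ParticipantRecord:
    """One participant of the cohort.

    ``gender`` follows the source coding 1 = Male, 0 = Female.  ``bari`` is
    the brachial artery relaxation index in seconds when derivable.
    """

    id: str
    group: str = "HV"
    apd_baseline: float | None = None
    apd_followup: float | None = None
    days_elapsed: float | None = None
    bari: float | None = None
    demographics: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("apd_baseline", "apd_followup"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be > 0 when present")
        if self.days_elapsed is not None and not self.days_elapsed > 0:
            raise ValueError("days_elapsed must be > 0 when present")
        if self.group not in _GROUPS:
            raise ValueError(f"group must be one of {_GROUPS}")


# --------------------------------------------------------------------------
# Cine I/O
# --------------------------------------------------------------------------

def _dicom_frame_interval(ds) -> float:
    """Frame interval in seconds from a DICOM dataset; raise when absent."""
    ft = ds.get("FrameTime")
    if ft is not None:
        return float(ft) / 1000.0
    ftv = ds.get("FrameTimeVector")
    if ftv is not None:
        vals = np.asarray([float(v) for v in ftv], dtype=float)
        inc = vals[1:] if vals.size > 1 and vals[0] == 0 else vals
        if inc.size and np.allclose(inc, inc.flat[0]):
            return float(inc.flat[0]) / 1000.0
        raise CineMetadataError("FrameTimeVector is not uniform")
    cr = ds.get("CineRate")
    if cr is not None and float(cr) > 0:
        return 1.0 / float(cr)
    raise CineMetadataError(
        "missing frame timing attribute: FrameTime (0018,1063)"
    )


def _dicom_pixel_spacing(ds) -> tuple[float, float]:
    ps = ds.get("PixelSpacing")
    if ps is None:
        # per-frame functional groups dialect
        try:
            shared = ds.SharedFunctionalGroupsSequence[0]
            ps = shared.PixelMeasuresSequence[0].PixelSpacing
        except (AttributeError, IndexError):
            ps = None
    if ps is None:
        raise CineMetadataError(
            "missing pixel spacing attribute: PixelSpacing (0028,0030)"
        )
    return float(ps[0]), float(ps[1])


def read_cine(path: str | Path, format_hint: str | None = None) -> CineLoop:
    """Read a cine loop from multi-frame DICOM or a TIFF stack + JSON sidecar.

    Parameters
    ----------
    path
        ``.dcm`` file, or a multi-page ``.tif``/``.tiff`` whose sidecar
        ``<stem>.json`` provides ``pixel_spacing`` (mm/px) and
        ``frame_interval`` (s).
    format_hint
        ``"dicom"`` or ``"stack"``; inferred from the suffix when omitted.

    Missing spacing or timing metadata raises :class:`CineMetadataError`
    naming the absent attribute — it is never silently defaulted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint
    if fmt is None:
        fmt = "stack" if path.suffix.lower() in (".tif", ".tiff") else "dicom"

    if fmt == "dicom":
        import pydicom

        ds = pydicom.dcmread(str(path))
        frames = ds.pixel_array
        if frames.ndim == 2:
            raise CineFormatError(f"{path} holds a single frame, not a loop")
        return CineLoop(
            frames=frames,
            pixel_spacing=_dicom_pixel_spacing(ds),
            frame_interval=_dicom_frame_interval(ds),
            source_id=str(ds.get("SeriesDescription",
                                 ds.get("SeriesInstanceUID", path.stem))),
        )
    if fmt == "stack":
        import tifffile

        frames = tifffile.imread(str(path))
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise CineMetadataError(f"sidecar metadata file {sidecar} not found")
        meta = json.loads(sidecar.read_text())
        for key in ("pixel_spacing", "frame_interval"):
            if key not in meta:
                raise CineMetadataError(f"sidecar missing attribute: {key}")
        return CineLoop(
            frames=frames,
            pixel_spacing=tuple(meta["pixel_spacing"]),
            frame_interval=meta["frame_interval"],
            source_id=meta.get("source_id", path.stem),
        )
    raise ValueError(f"unknown format_hint {format_hint!r}")


def write_cine(loop: CineLoop, path: str | Path) -> Path:
    """Write a loop as multi-frame grayscale DICOM (or TIFF stack + sidecar).

    Integer-typed frames round-trip bit-exactly through :func:`read_cine`;
    spacing and timing metadata round-trip to better than 1e-9.  Only the
    minimal image module is written — no clinical metadata.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), loop.frames)
        meta = {
            "pixel_spacing": list(loop.pixel_spacing),
            "frame_interval": loop.frame_interval,
            "source_id": loop.source_id,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
        return path

    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    frames = loop.frames
    if frames.dtype == np.uint8:
        bits = 8
    else:
        if not np.issubdtype(frames.dtype, np.integer):
            raise ValueError(
                "write_cine stores integer grayscale; quantize frames first"
            )
        frames = frames.astype(np.uint16)
        bits = 16

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID(
        "1.2.840.10008.5.1.4.1.1.3.1"  # Ultrasound Multi-frame Image Storage
    )
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = generate_uid()
    ds.SeriesDescription = loop.source_id[:64]
    ds.Modality = "US"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.NumberOfFrames = loop.n_frames
    ds.Rows, ds.Columns = loop.frame_shape
    ds.BitsAllocated = bits
    ds.BitsStored = bits
    ds.HighBit = bits - 1
    ds.PixelRepresentation = 0
    ds.PixelSpacing = [repr(loop.pixel_spacing[0]), repr(loop.pixel_spacing[1])]
    ds.FrameTime = repr(loop.frame_interval * 1000.0)  # milliseconds
    ds.PixelData = np.ascontiguousarray(frames).tobytes()
    ds.save_as(str(path), enforce_file_format=True)
    return path


# --------------------------------------------------------------------------
# Trace / diameter-map serialization
# --------------------------------------------------------------------------
#
# Delimited text: one row per lateral position, one column per frame, with a
# '#'-prefixed JSON header carrying the time base and units.  QC-masked cells
# are written as NaN and survive the round trip.

_TRACE_MAGIC = "# bari-traces v1"


def write_traces(obj, path: str | Path) -> Path:
    """Serialize a ``WallTraces`` or ``DiameterMap`` to delimited text."""
    path = Path(path)
    meta: dict[str, Any] = {
        "frame_interval": float(obj.frame_interval),
        "pixel_spacing": [float(s) for s in obj.pixel_spacing],
        "n_frames": int(obj.n_frames),
        "units": {"x_mm": "mm", "time": "s"},
    }
    cols = [f"f{j}" for j in range(obj.n_frames)]
    if hasattr(obj, "y_t"):  # WallTraces
        meta["kind"] = "wall_traces"
        meta["units"]["value"] = "px (row)"
        blocks = [("y_t", obj.y_t), ("y_b", obj.y_b),
                  ("qc", obj.qc_mask.astype(float))]
    else:  # DiameterMap
        meta["kind"] = "diameter_map"
        meta["units"]["value"] = "mm"
        blocks = [("d", obj.d)]
    rows = []
    for name, mat in blocks:
        for i, x in enumerate(obj.x_px):
            rows.append([name, int(x), float(obj.x_mm[i]), *mat[i, :]])
    df = pd.DataFrame(rows, columns=["component", "x_px", "x_mm", *cols])
    with open(path, "w") as fh:
        fh.write(_TRACE_MAGIC + "\n")
        fh.write("# " + json.dumps(meta) + "\n")
        df.to_csv(fh, index=False)
    return path


def read_traces(path: str | Path):
    """Read back what :func:`write_traces` wrote (lossless to 1e-9)."""
    path = Path(path)
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != _TRACE_MAGIC:
            raise ValueError(f"{path} is not a bari trace file")
        meta = json.loads(fh.readline().lstrip("# "))
        df = pd.read_csv(fh)
    vals = df.filter(regex=r"^f\d+$").to_numpy(dtype=float)
    x_px = df.loc[df["component"] == df["component"].iloc[0], "x_px"].to_numpy()
    x_mm = df.loc[df["component"] == df["component"].iloc[0], "x_mm"].to_numpy(
        dtype=float
    )
    spacing = tuple(meta["pixel_spacing"])
    interval = meta["frame_interval"]
    if meta["kind"] == "wall_traces":
        from .segmentation import WallTraces

        nx = len(x_px)
        y_t = vals[df["component"] == "y_t"]
        y_b = vals[df["component"] == "y_b"]
        qc = vals[df["component"] == "qc"].astype(bool)
        assert y_t.shape[0] == nx
        return WallTraces(
            x_px=x_px, x_mm=x_mm, y_t=y_t, y_b=y_b, qc_mask=qc,
            pixel_spacing=spacing, frame_interval=interval,
        )
    from .wall_dynamics import DiameterMap

    return DiameterMap(
        x_px=x_px, x_mm=x_mm, d=vals,
        pixel_spacing=spacing, frame_interval=interval,
    )


# --------------------------------------------------------------------------
# Cohort tables
# --------------------------------------------------------------------------

#: Canonical column dictionary.  Keys are canonical names; values are the
#: header aliases recognised after lower-casing and squashing non-alphanumeric
#: characters to "_".
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "id": ("id", "participant", "participant_id", "patient", "patient_id",
           "subject", "subject_id"),
    "group": ("group", "cohort", "size_group"),
    "apd_baseline": ("apd_baseline", "apd", "baseline_apd", "ap_diameter",
                     "aaa_size", "aaa_size_mm", "apd_mm", "size_mm"),
    "apd_followup": ("apd_followup", "followup_apd", "apd_12m",
                     "apd_follow_up", "followup_size_mm"),
    "days_elapsed": ("days_elapsed", "days", "days_lapsed", "followup_days",
                     "days_between_scans"),
    "bari": ("bari", "bari_s", "relaxation_index"),
    "gender": ("gender", "sex"),
    "bmi": ("bmi",),
    "map": ("map", "mean_arterial_pressure"),
    "htn": ("htn", "hypertension"),
}


def _canon(name: str) -> str:
    out = "".join(c if c.isalnum() else "_" for c in str(name).strip().lower())
    while "__" in out:
        out = out.replace("__", "_")
    return out.strip("_")


def _as_float(value, column: str):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise CohortTableError(f"non-numeric value {value!r} in column {column!r}")


def read_cohort_table(path: str | Path) -> list[ParticipantRecord]:
    """Read a cohort spreadsheet (CSV/TSV/XLSX) into participant records.

    Column headers are matched case-insensitively against
    :data:`COLUMN_ALIASES`; unknown columns are preserved verbatim in each
    record's ``demographics`` dict.  The size group is derived from the
    baseline anteroposterior diameter when no group column is given; rows
    without follow-up keep baseline-only status.  An empty table yields an
    empty list.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep)
    if df.empty:
        return []

    colmap: dict[str, str] = {}
    for col in df.columns:
        c = _canon(col)
        for canonical, aliases in COLUMN_ALIASES.items():
            if c in aliases and canonical not in colmap:
                colmap[canonical] = col
                break
    if "id" not in colmap:
        raise CohortTableError("cohort table has no participant id column")

    known = set(colmap.values())
    records = []
    for _, row in df.iterrows():
        apd = _as_float(row.get(colmap.get("apd_baseline")), "apd_baseline") \
            if "apd_baseline" in colmap else None
        if "group" in colmap and isinstance(row[colmap["group"]], str) \
                and row[colmap["group"]].strip():
            group = row[colmap["group"]].strip()
            if group not in _GROUPS:
                group = group_from_apd(apd)
        else:
            group = group_from_apd(apd)
        demo = {c: row[c] for c in df.columns if c not in known}
        for canonical in ("gender", "bmi", "map", "htn"):
            if canonical in colmap:
                demo[canonical] = row[colmap[canonical]]
        records.append(ParticipantRecord(
            id=str(row[colmap["id"]]),
            group=group,
            apd_baseline=apd,
            apd_followup=_as_float(row.get(colmap.get("apd_followup")),
                                   "apd_followup")
            if "apd_followup" in colmap else None,
            days_elapsed=_as_float(row.get(colmap.get("days_elapsed")),
                                   "days_elapsed")
            if "days_elapsed" in colmap else None,
            bari=_as_float(row.get(colmap.get("bari")), "bari")
            if "bari" in colmap else None,
            demographics=demo,
        ))
    return records
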