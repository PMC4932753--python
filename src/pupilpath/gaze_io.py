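"""Readers, writers and validated containers for eye-tracking study artifacts.

A study on disk is a collection of plain-text files:

* gaze logs       -- one delimited file per participant x case trial with
                     columns ``t, x, y, diameter, validity`` (names
                     configurable via :class:`GazeDialect`);
* viewport logs   -- timestamped zoom/pan states of the slide viewer;
* ROI sets        -- JSON polygons in slide coordinates, one file per case;
* case metadata   -- one delimited table of diagnoses, ratings, expertise;
* luminance traces -- optional ``t, intensity`` tables of mean screen
                     grayscale per captured frame.

Coordinate conventions (fixed here, reused everywhere): screen origin is
the top-left corner of a 1920 x 1080 display, y grows downward; slide
coordinates are base-resolution pixels at 1x magnification, origin
top-left; the viewport maps ``slide = origin + screen / zoom``.

Timestamps are milliseconds since trial start, stored as floats.  After
validation a recording is treated as uniformly sampled at its nominal
rate, and all downstream windowing is defined on sample indices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .errors import FormatError, ValidationError


def _csv_float(v) -> str:
    """Shortest round-trip decimal repr for CSV output."""
    return repr(float(v))

SCREEN_WIDTH = 1920
SCREEN_HEIGHT = 1080

#: The four diagnostic categories of the breast-biopsy assessment task.
DX_CATEGORIES = ("benign", "atypia", "dcis", "invasive")

EXPERTISE_LEVELS = ("resident", "faculty")

#: Inter-sample interval may deviate from 1000/rate by at most this factor.
RATE_TOLERANCE = 0.2


# ---------------------------------------------------------------------------
# gaze recordings
# ---------------------------------------------------------------------------

@dataclass
class GazeDialect:
    """Column naming / separator conventions of a gaze log file."""

    t: str = "t"
    x: str = "x"
    y: str = "y"
    d: str = "diameter"
    valid: str = "validity"
    sep: str | None = None  # None: sniff comma vs tab from the header line


@dataclass
class GazeRecording:
    """One participant x case trial of raw eye-tracker output.

    Samples are stored as parallel arrays.  A sample is *null* (no usable
    pupil measurement, typically a blink) iff its validity flag is false
    or its diameter is <= 0; both encodings collapse to one internal null
    state exposed as :attr:`null_mask`.
    """

    participant_id: str
    case_id: str
    t: np.ndarray        # ms since trial start
    x: np.ndarray        # screen px
    y: np.ndarray        # screen px
    d: np.ndarray        # pupil diameter, eye-camera px
    valid: np.ndarray    # bool validity flag as logged
    nominal_rate: float = 60.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.d) == len(self.valid) == n):
            raise ValidationError("gaze sample arrays have unequal lengths")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def null_mask(self) -> np.ndarray:
        """True where the sample carries no usable pupil measurement."""
        return ~self.valid | (self.d <= 0) | ~np.isfinite(self.d)

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.nominal_rate

    def validate(self) -> "GazeRecording":
        """Check timestamp monotonicity and sampling-rate consistency.

        Raises
        ------
        ValidationError
            If timestamps are not strictly increasing (the message names
            the first offending 1-based data row) or an inter-sample
            interval deviates from the nominal period by more than 20%.
        """
        if len(self) == 0:
            raise ValidationError("empty recording")
        if np.any(self.t < 0):
            raise ValidationError("negative timestamps")
        dt = np.diff(self.t)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            row = int(bad[0]) + 2  # +1 for 0-base, +1 for the first row
            raise ValidationError(
                f"timestamps not strictly increasing at data row {row}"
            )
        period = self.period_ms
        off = np.nonzero(np.abs(dt - period) > RATE_TOLERANCE * period)[0]
        if off.size:
            row = int(off[0]) + 2
            raise ValidationError(
                f"inter-sample interval outside +/-20% of nominal "
                f"{period:.3f} ms at data row {row}"
            )
        return self


def read_gaze_log(
    path: str | Path,
    dialect: GazeDialect | None = None,
    participant_id: str = "",
    case_id: str = "",
    nominal_rate: float = 60.0,
) -> GazeRecording:
    """Parse and validate one delimited gaze log.

    Null/invalid samples are retained (with ``valid=False``); rows whose
    diameter is <= 0 are marked invalid per the package's null encoding.
    """
    dialect = dialect or GazeDialect()
    path = Path(path)
    sep = dialect.sep
    if sep is None:
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    cols = {dialect.t, dialect.x, dialect.y, dialect.d, dialect.valid}
    missing = cols - set(df.columns)
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {sorted(missing)}")
    valid = df[dialect.valid]
    if valid.dtype == object:
        valid = valid.astype(str).str.strip().str.lower().isin(
            {"1", "true", "t", "yes"}
        )
    valid = valid.astype(bool).to_numpy()
    d = df[dialect.d].to_numpy(dtype=float)
    valid = valid & (d > 0) & np.isfinite(d)
    rec = GazeRecording(
        participant_id=participant_id,
        case_id=case_id,
        t=df[dialect.t].to_numpy(dtype=float),
        x=df[dialect.x].to_numpy(dtype=float),
        y=df[dialect.y].to_numpy(dtype=float),
        d=d,
        valid=valid,
        nominal_rate=nominal_rate,
    )
    return rec.validate()


def write_gaze_log(rec: GazeRecording, path: str | Path,
                   dialect: GazeDialect | None = None) -> None:
    dialect = dialect or GazeDialect()
    sep = dialect.sep or ","
    df = pd.DataFrame({
        dialect.t: rec.t,
        dialect.x: rec.x,
        dialect.y: rec.y,
        dialect.d: rec.d,
        dialect.valid: rec.valid.astype(int),
    })
    df.to_csv(path, sep=sep, index=False, float_format=_csv_float)


# ---------------------------------------------------------------------------
# viewport traces
# ---------------------------------------------------------------------------

ZOOM_MIN, ZOOM_MAX = 1.0, 60.0


@dataclass(frozen=True)
class ViewportState:
    """Slide-viewer state: magnification and the slide coordinate of the
    screen's top-left corner.  Piecewise constant until the next state."""

    t_start: float
    zoom: float
    origin_x: float
    origin_y: float


@dataclass
class ViewportTrace:
    states: list[ViewportState]

    def __post_init__(self) -> None:
        if not self.states:
            raise ValidationError("viewport trace has no states")
        ts = [s.t_start for s in self.states]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValidationError("viewport states not strictly increasing in t")
        for s in self.states:
            if not (ZOOM_MIN <= s.zoom <= ZOOM_MAX):
                raise ValidationError(
                    f"zoom {s.zoom} outside [{ZOOM_MIN:g}, {ZOOM_MAX:g}]"
                )
        self._t = np.array(ts, dtype=float)

    def state_at(self, t: float) -> ViewportState:
        """Latest state with ``t_start <= t`` (right-open intervals)."""
        idx = int(np.searchsorted(self._t, t, side="right")) - 1
        if idx < 0:
            raise ValidationError(
                f"viewport state undefined before first log entry (t={t})"
            )
        return self.states[idx]


def read_viewport_log(path: str | Path) -> ViewportTrace:
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    needed = {"t", "zoom", "origin_x", "origin_y"}
    missing = needed - set(df.columns)
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {sorted(missing)}")
    states = [
        ViewportState(float(r.t), float(r.zoom), float(r.origin_x),
                      float(r.origin_y))
        for r in df.itertuples(index=False)
    ]
    return ViewportTrace(states)


def write_viewport_log(trace: ViewportTrace, path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.t_start, s.zoom, s.origin_x, s.origin_y) for s in trace.states],
        columns=["t", "zoom", "origin_x", "origin_y"],
    )
    df.to_csv(path, index=False, float_format=_csv_float)


# ---------------------------------------------------------------------------
# diagnostic regions of interest
# ---------------------------------------------------------------------------

@dataclass
class ROI:
    roi_id: str
    polygon: Polygon

    @property
    def vertices(self) -> list[list[float]]:
        return [[float(px), float(py)]
                for px, py in self.polygon.exterior.coords[:-1]]


@dataclass
class ROISet:
    """Diagnostic regions of interest for one case, in slide coordinates."""

    case_id: str
    rois: list[ROI]

    def __post_init__(self) -> None:
        if not self.rois:
            raise ValidationError(f"case {self.case_id}: needs at least one ROI")
        for roi in self.rois:
            if len(roi.polygon.exterior.coords) - 1 < 3:
                raise ValidationError(
                    f"ROI {roi.roi_id}: polygon needs >= 3 vertices"
                )
            if roi.polygon.area <= 0:
                raise ValidationError(f"ROI {roi.roi_id}: degenerate polygon")

    def containing(self, x: float, y: float) -> str | None:
        """Id of the first ROI whose polygon covers (x, y); boundary points
        count as inside."""
        pt = None
        for roi in self.rois:
            minx, miny, maxx, maxy = roi.polygon.bounds
            if not (minx <= x <= maxx and miny <= y <= maxy):
                continue
            pt = pt if pt is not None else Point(x, y)
            if roi.polygon.covers(pt):
                return roi.roi_id
        return None


def make_roi(roi_id: str, vertices: Sequence[Sequence[float]]) -> ROI:
    if len(vertices) < 3:
        raise ValidationError(f"ROI {roi_id}: polygon needs >= 3 vertices")
    return ROI(roi_id=roi_id, polygon=Polygon(vertices))


def read_roi_file(path: str | Path) -> ROISet:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    try:
        case_id = payload["case_id"]
        rois = [make_roi(r["roi_id"], r["vertices"]) for r in payload["rois"]]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{Path(path).name}: malformed ROI file ({exc})")
    return ROISet(case_id=case_id, rois=rois)


def write_roi_file(roi_set: ROISet, path: str | Path) -> None:
    payload = {
        "case_id": roi_set.case_id,
        "rois": [{"roi_id": r.roi_id, "vertices": r.vertices}
                 for r in roi_set.rois],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# case metadata
# ---------------------------------------------------------------------------

@dataclass
class CaseRecord:
    """One participant x case outcome row.

    ``agreement`` is derived: the participant's diagnosis matches the
    expert consensus reference diagnosis for the case.
    """

    participant_id: str
    case_id: str
    expertise: str
    consensus_dx: str
    participant_dx: str
    difficulty_rating: int

    def __post_init__(self) -> None:
        self.expertise = self.expertise.lower()
        self.consensus_dx = self.consensus_dx.lower()
        self.participant_dx = self.participant_dx.lower()
        if self.expertise not in EXPERTISE_LEVELS:
            raise ValidationError(f"unknown expertise {self.expertise!r}")
        for dx in (self.consensus_dx, self.participant_dx):
            if dx not in DX_CATEGORIES:
                raise ValidationError(f"unknown diagnosis {dx!r}")
        if not (isinstance(self.difficulty_rating, (int, np.integer))
                and 1 <= self.difficulty_rating <= 6):
            raise ValidationError(
                f"difficulty rating {self.difficulty_rating!r} not in 1..6"
            )
        self.difficulty_rating = int(self.difficulty_rating)

    @property
    def agreement(self) -> bool:
        return self.participant_dx == self.consensus_dx


METADATA_COLUMNS = ["participant_id", "case_id", "expertise",
                    "consensus_dx", "participant_dx", "difficulty_rating"]


def read_case_metadata(path: str | Path) -> list[CaseRecord]:
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {sorted(missing)}")
    return [
        CaseRecord(
            participant_id=str(r.participant_id),
            case_id=str(r.case_id),
            expertise=str(r.expertise),
            consensus_dx=str(r.consensus_dx),
            participant_dx=str(r.participant_dx),
            difficulty_rating=int(r.difficulty_rating),
        )
        for r in df.itertuples(index=False)
    ]


def write_case_metadata(records: Sequence[CaseRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.participant_id, r.case_id, r.expertise, r.consensus_dx,
          r.participant_dx, r.difficulty_rating) for r in records],
        columns=METADATA_COLUMNS,
    )
    df.to_csv(path, index=False, float_format=_csv_float)


# ---------------------------------------------------------------------------
# luminance traces
# ---------------------------------------------------------------------------

@dataclass
class LuminanceTrace:
    """Mean screen grayscale per captured frame, step-interpolated in time."""

    t: np.ndarray          # frame time, ms
    intensity: np.ndarray  # mean grayscale in (0, 1]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.t) != len(self.intensity) or len(self.t) == 0:
            raise ValidationError("luminance trace must be non-empty and aligned")
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError("luminance frame times must strictly increase")
        if np.any(self.intensity <= 0) or np.any(self.intensity > 1):
            raise ValidationError("luminance intensities must lie in (0, 1]")

    def intensity_at(self, t: np.ndarray | float) -> np.ndarray:
        """Intensity of the latest frame at or before t (video semantics)."""
        idx = np.searchsorted(self.t, np.asarray(t, dtype=float), side="right") - 1
        if np.any(idx < 0):
            raise ValidationError("luminance trace does not cover requested time")
        return self.intensity[idx]


def read_luminance_trace(path: str | Path) -> LuminanceTrace:
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = {"t", "intensity"} - set(df.columns)
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {sorted(missing)}")
    return LuminanceTrace(t=df["t"].to_numpy(float),
                          intensity=df["intensity"].to_numpy(float))


def write_luminance_trace(trace: LuminanceTrace, path: str | Path) -> None:
    pd.DataFrame({"t": trace.t, "intensity": trace.intensity}).to_csv(
        path, index=False, float_format=_csv_float
    )


# ---------------------------------------------------------------------------
# tidy output tables
# ---------------------------------------------------------------------------

def write_trial_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy per-trial (or per-cell) feature table as CSV.

    Floats are written with shortest round-trip repr, so
    write -> read -> write is lossless.
    """
    df.to_csv(path, index=False, float_format=_csv_float)


def read_trial_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
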