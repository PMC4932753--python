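"""Dispersion-threshold (I-DT) fixation detection and ROI hit-testing.

Raw gaze is classified into fixations and saccades with the classic
I-DT scheme: a maximal run of consecutive samples whose spatial
dispersion ``(max x - min x) + (max y - min y)`` stays within a
threshold, and whose duration reaches a minimum, becomes a fixation
with centroid at the mean sample position; everything else is
saccade/unclassified.  Defaults (41 px dispersion, 100 ms minimum) are
about 1 degree of visual angle on a 22-inch 1920x1080 display viewed at
60 cm, and are configurable.

Fixation centroids are mapped from screen to slide coordinates through
the viewport state at fixation *onset* (a fixation spanning a pan/zoom
change is anchored at its onset), then tested against the case's
diagnostic ROIs; a centroid on a polygon boundary counts as inside.
The first fixation landing in any diagnostic ROI defines the phasic
event for the trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .gaze_io import ROISet, ViewportState, ViewportTrace
from .preprocess import CleanRecording

DEFAULT_DISPERSION_PX = 41.0
DEFAULT_MIN_DURATION_MS = 100.0

#: A fixation whose samples are mostly blink-interpolated is kept but flagged.
INTERPOLATED_FLAG_FRACTION = 0.5


def _idt_segments_py(x, y, n_min, dispersion):
    """Greedy maximal-window I-DT scan; returns (starts, ends) index arrays,
    ends exclusive."""
    n = x.shape[0]
    starts = np.empty(n, np.int64)
    ends = np.empty(n, np.int64)
    m = 0
    i = 0
    while i + n_min <= n:
        xmin = xmax = x[i]
        ymin = ymax = y[i]
        for k in range(i + 1, i + n_min):
            if x[k] < xmin:
                xmin = x[k]
            elif x[k] > xmax:
                xmax = x[k]
            if y[k] < ymin:
                ymin = y[k]
            elif y[k] > ymax:
                ymax = y[k]
        if (xmax - xmin) + (ymax - ymin) > dispersion:
            i += 1
            continue
        j = i + n_min
        while j < n:
            nxmin = min(xmin, x[j])
            nxmax = max(xmax, x[j])
            nymin = min(ymin, y[j])
            nymax = max(ymax, y[j])
            if (nxmax - nxmin) + (nymax - nymin) > dispersion:
                break
            xmin, xmax, ymin, ymax = nxmin, nxmax, nymin, nymax
            j += 1
        starts[m] = i
        ends[m] = j
        m += 1
        i = j
    return starts[:m], ends[:m]


try:  # JIT-compile the hot loop when numba is available
    from numba import njit

    _idt_segments = njit(cache=True)(_idt_segments_py)
except Exception:  # pragma: no cover - exercised only without numba
    _idt_segments = _idt_segments_py


@dataclass
class Fixation:
    """A classified fixation.  ``offset_index`` is exclusive; duration is
    ``(n_samples - 1) * sample period``."""

    onset_index: int
    offset_index: int
    onset_t: float
    centroid_screen: tuple[float, float]
    duration_ms: float
    interpolated_fraction: float = 0.0
    flagged: bool = False
    centroid_slide: tuple[float, float] | None = None
    roi_id: str | None = None

    @property
    def n_samples(self) -> int:
        return self.offset_index - self.onset_index


@dataclass
class DroiEvent:
    """The first fixation of a trial inside a diagnostic ROI."""

    participant_id: str
    case_id: str
    event_index: int       # sample index of the fixation onset
    roi_id: str
    fixation_number: int   # position within the trial's fixation sequence


def detect_fixations(
    clean: CleanRecording,
    dispersion_px: float = DEFAULT_DISPERSION_PX,
    min_duration_ms: float = DEFAULT_MIN_DURATION_MS,
) -> list[Fixation]:
    """Classify a clean recording into fixations via I-DT.

    The minimum duration is converted to a minimum window of
    ``round(min_duration_ms / period) + 1`` samples so that the spanned
    time (``(n-1) * period``) reaches ``min_duration_ms``.
    """
    if len(clean) == 0:
        raise ValidationError("empty recording")
    if dispersion_px <= 0:
        raise ValidationError("dispersion threshold must be positive")
    period = clean.period_ms
    if min_duration_ms < period:
        raise ValidationError("min duration shorter than one sample period")
    n_min = int(round(min_duration_ms / period)) + 1
    starts, ends = _idt_segments(
        np.ascontiguousarray(clean.x, dtype=np.float64),
        np.ascontiguousarray(clean.y, dtype=np.float64),
        n_min,
        float(dispersion_px),
    )
    # segment means via cumulative sums (cheap for thousands of fixations)
    csx = np.concatenate(([0.0], np.cumsum(clean.x)))
    csy = np.concatenate(([0.0], np.cumsum(clean.y)))
    csm = np.concatenate(([0.0], np.cumsum(clean.interpolated_mask,
                                           dtype=float)))
    fixations: list[Fixation] = []
    for s, e in zip(starts.tolist(), ends.tolist()):
        ln = e - s
        frac = (csm[e] - csm[s]) / ln
        fixations.append(Fixation(
            onset_index=s,
            offset_index=e,
            onset_t=float(clean.t[s]),
            centroid_screen=((csx[e] - csx[s]) / ln, (csy[e] - csy[s]) / ln),
            duration_ms=(ln - 1) * period,
            interpolated_fraction=frac,
            flagged=frac > INTERPOLATED_FLAG_FRACTION,
        ))
    return fixations


def screen_to_slide(
    point_screen: tuple[float, float], state: ViewportState
) -> tuple[float, float]:
    """Map a screen-pixel point into slide coordinates:
    ``slide = origin + screen / zoom``."""
    sx, sy = point_screen
    return (state.origin_x + sx / state.zoom,
            state.origin_y + sy / state.zoom)


def assign_roi(
    fixation: Fixation,
    roi_set: ROISet,
    viewport: ViewportTrace,
) -> str | None:
    """ROI membership of a fixation, or None.

    The centroid is mapped through the viewport state at fixation onset;
    the id of the first polygon covering it (boundary inclusive) is
    returned and the fixation annotated in place.
    """
    state = viewport.state_at(fixation.onset_t)
    slide_pt = screen_to_slide(fixation.centroid_screen, state)
    fixation.centroid_slide = slide_pt
    fixation.roi_id = roi_set.containing(*slide_pt)
    return fixation.roi_id


def first_droi_fixation(
    fixations: list[Fixation],
    roi_set: ROISet,
    viewport: ViewportTrace,
    participant_id: str = "",
    case_id: str = "",
) -> DroiEvent | None:
    """Earliest fixation inside any diagnostic ROI, or None.

    Trials without any dROI fixation are excluded from phasic analysis
    by the caller.
    """
    for k, fix in enumerate(fixations):
        roi_id = assign_roi(fix, roi_set, viewport)
        if roi_id is not None:
            return DroiEvent(
                participant_id=participant_id,
                case_id=case_id,
                event_index=fix.onset_index,
                roi_id=roi_id,
                fixation_number=k,
            )
    return None
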