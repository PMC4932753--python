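"""Event-locked (phasic) pupil responses at the first dROI fixation.

Around the first fixation inside a diagnostic ROI, a 306-sample window
is cut from the cleaned trace: 6 samples (100 ms) before the event and
300 samples (5 s) after.  The pre-event samples are averaged into a
baseline and all 300 post-event samples are referenced to it by
subtraction, giving relative diameter in camera pixels.  Windows whose
pre-interpolation null fraction exceeds 50% (strictly) are dropped.

Surviving trials are classified on two crossed axes: agreement of the
participant's diagnosis with the consensus reference (agree/disagree)
and rated difficulty dichotomized by a median split over the analyzed
trials (low/high, ties to low).  The relative trace is finally reduced
to 10 bins of 500 ms (30 samples) each.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InsufficientWindowError, ValidationError
from .gaze_io import CaseRecord
from .preprocess import CleanRecording
from .tables import CellTable, build_cell_table

PRE_SAMPLES = 6      # 100 ms at 60 Hz
POST_SAMPLES = 300   # 5 s at 60 Hz
WINDOW_SAMPLES = PRE_SAMPLES + POST_SAMPLES
N_PHASIC_BINS = 10
NULL_EXCLUSION_THRESHOLD = 0.5

#: 2 x 2 trial classification, in the order the design enumerates them.
TRIAL_TYPES = (
    "easy-disagree",
    "difficult-disagree",
    "easy-agree",
    "difficult-agree",
)


@dataclass
class PhasicTrace:
    """One trial's baseline-referenced event window."""

    participant_id: str
    case_id: str
    pre: np.ndarray          # 6 diameters before the event
    post: np.ndarray         # 300 diameters from the event on
    baseline: float          # mean(pre)
    relative: np.ndarray     # post - baseline, px
    null_fraction_window: float
    trial_type: str | None = None

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=float)
        self.post = np.asarray(self.post, dtype=float)
        self.relative = np.asarray(self.relative, dtype=float)
        if self.pre.shape != (PRE_SAMPLES,):
            raise ValidationError(f"pre window must have {PRE_SAMPLES} samples")
        if self.post.shape != (POST_SAMPLES,):
            raise ValidationError(f"post window must have {POST_SAMPLES} samples")
        if self.relative.shape != (POST_SAMPLES,):
            raise ValidationError("relative trace length mismatch")
        if not 0.0 <= self.null_fraction_window <= 1.0:
            raise ValidationError("null fraction outside [0, 1]")

    @property
    def bins(self) -> np.ndarray:
        return phasic_bins(self.relative)


def extract_event_window(
    clean: CleanRecording,
    event_index: int,
    pre_samples: int = PRE_SAMPLES,
    post_samples: int = POST_SAMPLES,
) -> PhasicTrace:
    """Cut and baseline-reference the event window of one trial.

    ``pre`` covers samples ``[event - 6, event)``, ``post`` covers
    ``[event, event + 300)``.  The window null fraction is computed over
    all 306 positions from the pre-interpolation null mask.

    Raises
    ------
    InsufficientWindowError
        If the event sits closer than 6 samples to the start or 300
        samples to the end of the recording; callers skip such trials.
    """
    n = len(clean)
    if event_index < pre_samples or event_index + post_samples > n:
        raise InsufficientWindowError(
            f"{clean.participant_id}/{clean.case_id}: event at sample "
            f"{event_index} leaves an incomplete {pre_samples}+{post_samples} "
            f"window in a {n}-sample recording"
        )
    pre = clean.d[event_index - pre_samples:event_index]
    post = clean.d[event_index:event_index + post_samples]
    baseline = float(pre.mean())
    null = clean.null_mask[event_index - pre_samples:event_index + post_samples]
    return PhasicTrace(
        participant_id=clean.participant_id,
        case_id=clean.case_id,
        pre=pre.copy(),
        post=post.copy(),
        baseline=baseline,
        relative=post - baseline,
        null_fraction_window=float(null.mean()),
    )


def exclude_high_null(trace: PhasicTrace,
                      threshold: float = NULL_EXCLUSION_THRESHOLD) -> bool:
    """True if the trial is kept: dropped iff the window null fraction
    strictly exceeds the threshold (exactly 50% is kept)."""
    return not (trace.null_fraction_window > threshold)


def difficulty_median(ratings: Sequence[int]) -> float:
    """Median of the analyzed trials' difficulty ratings (pooled)."""
    if len(ratings) == 0:
        raise ValidationError("no ratings to take a median over")
    return float(np.median(np.asarray(ratings, dtype=float)))


def classify_trial(case: CaseRecord, median: float,
                   ties: str = "low") -> str:
    """Assign one of the four trial types from agreement and a median
    split on rated difficulty.  Ratings exactly at the median go to
    'low' by default ('high' available via ``ties``)."""
    if ties not in ("low", "high"):
        raise ValidationError(f"unknown tie rule {ties!r}")
    r = case.difficulty_rating
    low = r <= median if ties == "low" else r < median
    side = "easy" if low else "difficult"
    outcome = "agree" if case.agreement else "disagree"
    return f"{side}-{outcome}"


def phasic_bins(relative: np.ndarray,
                n_bins: int = N_PHASIC_BINS) -> np.ndarray:
    """Mean relative diameter over blocks [0, 30), [30, 60), ...
    (500 ms each at 60 Hz)."""
    x = np.asarray(relative, dtype=float)
    if x.ndim != 1 or x.size != POST_SAMPLES:
        raise ValidationError(
            f"expected {POST_SAMPLES} relative samples, got {x.size}"
        )
    return x.reshape(n_bins, -1).mean(axis=1)


def build_phasic_table(traces: Sequence[PhasicTrace]) -> CellTable:
    """Participant x trial-type x bin cell means (pre-imputation).

    All traces must already be classified.
    """
    records = []
    for tr in traces:
        if tr.trial_type is None:
            raise ValidationError(
                f"{tr.participant_id}/{tr.case_id}: trial not classified"
            )
        records.append((tr.participant_id, tr.trial_type, tr.bins))
    return build_cell_table(records, TRIAL_TYPES)
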