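"""Null-sample (blink) rectification and screen-luminance adjustment.

Eye blinks and tracking dropouts leave runs of null samples in the pupil
trace.  Interior runs are repaired by linear interpolation between the
nearest valid neighbours, in sample-index space (recordings are uniform
after validation); leading/trailing runs are filled with the nearest
valid value, which avoids extrapolation.  Gaze position is repaired the
same way so that fixation detection can bridge blinks.

Pupil diameter also responds to screen brightness.  The adjustment
multiplies each diameter by the mean grayscale intensity of the screen
frame on display at that moment (equivalently, divides by the reciprocal
of the intensity), so that dilation attributable to a darkening screen
is discounted.  The opposite convention -- dividing by intensity -- is
available via ``mode="divide"`` for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UnrecoverableTrialError, ValidationError
from .gaze_io import GazeRecording, LuminanceTrace


@dataclass
class CleanRecording:
    """A gaze recording after null rectification.

    ``d`` holds the working (interpolated, possibly luminance-adjusted)
    diameters; ``d_raw`` the interpolated but unadjusted ones.
    ``interpolated_mask`` marks samples that were null before repair, and
    ``null_fraction`` is their proportion, computed before filling.
    """

    participant_id: str
    case_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    d: np.ndarray
    d_raw: np.ndarray
    interpolated_mask: np.ndarray
    null_fraction: float
    nominal_rate: float = 60.0

    def __len__(self) -> int:
        return len(self.t)

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.nominal_rate

    @property
    def null_mask(self) -> np.ndarray:
        """Pre-interpolation null mask (alias of ``interpolated_mask``)."""
        return self.interpolated_mask


def interpolate_nulls(rec: GazeRecording) -> CleanRecording:
    """Rectify null samples by linear interpolation.

    Interior null runs are replaced by the straight line (in sample
    index) between the nearest valid neighbours; edge runs take the
    nearest valid value.  Diameter and gaze position are both repaired.

    Raises
    ------
    UnrecoverableTrialError
        If the recording contains no valid sample at all.
    """
    null = rec.null_mask
    good = ~null
    if not good.any():
        raise UnrecoverableTrialError(
            f"{rec.participant_id}/{rec.case_id}: no valid samples"
        )
    idx = np.arange(len(rec), dtype=float)
    gi = idx[good]

    def fill(values: np.ndarray) -> np.ndarray:
        # np.interp clamps outside the data range -> nearest-value edge fill
        return np.interp(idx, gi, values[good])

    d = fill(rec.d)
    return CleanRecording(
        participant_id=rec.participant_id,
        case_id=rec.case_id,
        t=rec.t.copy(),
        x=fill(rec.x),
        y=fill(rec.y),
        d=d,
        d_raw=d.copy(),
        interpolated_mask=null.copy(),
        null_fraction=float(null.mean()),
        nominal_rate=rec.nominal_rate,
    )


def adjust_for_luminance(
    clean: CleanRecording,
    luminance: LuminanceTrace,
    mode: str = "multiply",
) -> CleanRecording:
    """Adjust pupil diameter for screen brightness.

    Each sample's diameter is combined with the intensity ``I(t)`` of the
    latest screen frame at or before the sample time.  ``mode="multiply"``
    (default) computes ``d * I(t)``; ``mode="divide"`` computes
    ``d / I(t)``.  Original (unadjusted) diameters are retained in
    ``d_raw``.
    """
    if mode not in ("multiply", "divide"):
        raise ValidationError(f"unknown luminance mode {mode!r}")
    if luminance.t[0] > clean.t[0]:
        raise ValidationError(
            "luminance trace does not cover the start of the recording"
        )
    intensity = luminance.intensity_at(clean.t)
    d = clean.d_raw * intensity if mode == "multiply" else clean.d_raw / intensity
    return CleanRecording(
        participant_id=clean.participant_id,
        case_id=clean.case_id,
        t=clean.t,
        x=clean.x,
        y=clean.y,
        d=d,
        d_raw=clean.d_raw,
        interpolated_mask=clean.interpolated_mask,
        null_fraction=clean.null_fraction,
        nominal_rate=clean.nominal_rate,
    )


def mean_frame_intensity(image: np.ndarray) -> float:
    """Mean grayscale of one 2-D frame, rescaled to [0, 1].

    Accepts frames scaled either in [0, 255] or already in [0, 1].
    """
    arr = np.asarray(image, dtype=float)
    if arr.size == 0:
        raise ValidationError("empty frame")
    if arr.min() < 0:
        raise ValidationError("negative pixel values")
    m = float(arr.mean())
    if arr.max() > 1.0:
        m /= 255.0
    return m
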