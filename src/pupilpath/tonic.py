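"""Tonic pupil-diameter profiles conditioned on rated case difficulty.

Case interpretations differ in length, so each trial's full pupil trace
is time-normalized to a fixed 500 samples by band-limited trigonometric
(Fourier) interpolation -- the classic ``interpft`` resampling -- and
then reduced to 10 time-bin means of 50 samples each.  Tonic analysis
uses raw (not baseline-referenced) diameters.

Six-point difficulty ratings are collapsed to four conditions to even
out sparse scale endpoints: A = ratings 1-2, B = 3, C = 4, D = 5-6.
Missing participant x condition cells are filled with condition means
(see :mod:`pupilpath.tables`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .preprocess import CleanRecording
from .tables import CellTable, build_cell_table, impute_condition_means  # noqa: F401

#: Common trace length after time normalization (10 bins x 50 samples).
NORMALIZED_LENGTH = 500
N_TONIC_BINS = 10

DIFFICULTY_CONDITIONS = ("A", "B", "C", "D")

_RATING_TO_CONDITION = {1: "A", 2: "A", 3: "B", 4: "C", 5: "D", 6: "D"}

#: First-second baseline: mean of the first 60 samples at 60 Hz.
BASELINE_SAMPLES = 60


def fourier_resample(signal: np.ndarray, n_out: int) -> np.ndarray:
    """Band-limited trigonometric interpolation to ``n_out`` samples.

    Forward DFT, symmetric spectrum zero-padding (splitting the Nyquist
    coefficient when lengthening an even-length signal) or truncation
    (folding the conjugate pair into a real Nyquist bin when shortening
    to even length), inverse DFT scaled by ``n_out / n_in``.  Preserves
    the signal mean exactly for any lengths.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("signal must be 1-D with length >= 2")
    if n_out < 2:
        raise ValidationError("n_out must be >= 2")
    if not np.all(np.isfinite(x)):
        raise ValidationError("signal contains non-finite values")
    n_in = x.size
    if n_out == n_in:
        return x.copy()
    X = np.fft.fft(x)
    Y = np.zeros(n_out, dtype=complex)
    if n_out > n_in:
        h = n_in // 2
        if n_in % 2 == 0:
            Y[:h] = X[:h]
            Y[h] = X[h] / 2.0
            Y[n_out - h] = X[h] / 2.0
            if h > 1:
                Y[n_out - h + 1:] = X[h + 1:]
        else:
            Y[:h + 1] = X[:h + 1]
            Y[n_out - h:] = X[h + 1:]
    else:
        h = n_out // 2
        if n_out % 2 == 0:
            Y[:h] = X[:h]
            Y[h] = X[h] + X[n_in - h]   # conjugate pair -> real Nyquist
            Y[h + 1:] = X[n_in - h + 1:]
        else:
            Y[:h + 1] = X[:h + 1]
            Y[h + 1:] = X[n_in - h:]
    return np.fft.ifft(Y).real * (n_out / n_in)


def tonic_bins(signal: np.ndarray, n_bins: int = N_TONIC_BINS) -> np.ndarray:
    """Reduce a normalized-length trace to bin means over half-open
    index blocks [0, 50), [50, 100), ..."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size != NORMALIZED_LENGTH:
        raise ValidationError(
            f"expected a length-{NORMALIZED_LENGTH} normalized trace, "
            f"got {x.size}"
        )
    return x.reshape(n_bins, -1).mean(axis=1)


def collapse_difficulty(rating: int) -> str:
    """Collapse a 1-6 difficulty rating to condition A/B/C/D."""
    if not (isinstance(rating, (int, np.integer)) and 1 <= rating <= 6):
        raise ValidationError(f"rating {rating!r} not an integer in 1..6")
    return _RATING_TO_CONDITION[int(rating)]


def baseline_first_second(clean: CleanRecording,
                          n_samples: int = BASELINE_SAMPLES) -> float:
    """Mean interpolated diameter over the first second of interpretation."""
    if len(clean) < n_samples:
        raise ValidationError(
            f"recording shorter than {n_samples} samples"
        )
    return float(clean.d[:n_samples].mean())


@dataclass
class TonicProfile:
    """One trial's normalized tonic profile."""

    participant_id: str
    case_id: str
    condition: str
    bins: np.ndarray        # 10 mean diameters, camera px
    baseline_1s: float

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        if self.bins.shape != (N_TONIC_BINS,):
            raise ValidationError("tonic profile needs exactly 10 bins")
        if not np.all(np.isfinite(self.bins)):
            raise ValidationError("tonic bins must be finite")
        if self.condition not in DIFFICULTY_CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")


def tonic_profile(clean: CleanRecording, rating: int) -> TonicProfile:
    """Normalize one trial and reduce it to a tonic profile."""
    resampled = fourier_resample(clean.d, NORMALIZED_LENGTH)
    return TonicProfile(
        participant_id=clean.participant_id,
        case_id=clean.case_id,
        condition=collapse_difficulty(rating),
        bins=tonic_bins(resampled),
        baseline_1s=baseline_first_second(clean),
    )


def build_tonic_table(profiles: Sequence[TonicProfile]) -> CellTable:
    """Participant x condition x bin cell means (pre-imputation)."""
    return build_cell_table(
        [(p.participant_id, p.condition, p.bins) for p in profiles],
        DIFFICULTY_CONDITIONS,
    )
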