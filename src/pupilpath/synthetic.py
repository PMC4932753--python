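"""Synthetic whole-slide-reading studies with known planted effects.

The generator emulates the recordings of a pathology eye-tracking study:
per-trial 60 Hz gaze logs, viewport (zoom/pan) logs, diagnostic ROI
polygons, case metadata with difficulty ratings and diagnoses, and
per-trial screen-luminance traces -- everything the readers in
:mod:`pupilpath.gaze_io` consume -- together with a truth record of the
planted quantities for parameter-recovery tests.

Model per trial
---------------
* Gaze is a scanpath of fixation clusters (small Gaussian jitter around
  a cluster centre) separated by short saccades (linear sweeps);
  consecutive centres are kept >= 150 px apart so the fixation structure
  is unambiguous at the default dispersion threshold.
* Pupil diameter = participant baseline + tonic difficulty offset
  (``tonic_step`` x condition index) + AR(1) drift + an event-locked
  kernel at the scripted first-dROI-fixation sample + a term coupled to
  screen luminance.  The kernel amplitude is +A for difficult-agree
  trials, -A for difficult-disagree, 0 for easy trials.
* Blinks are inserted as null runs (validity false, diameter 0); a
  margin around the scripted dROI event is kept blink-free so the
  scripted event sample stays recoverable exactly.
* The viewport shows non-diagnostic slide regions before the event; at
  the event it jumps to a state centred on the ROI, so the scripted
  fixation -- and no earlier one -- maps inside the ROI polygon.

Determinism: one root seed; each trial draws from its own counter-keyed
substream, so trials are independent of generation order.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .errors import ValidationError
from .gaze_io import (
    SCREEN_HEIGHT,
    SCREEN_WIDTH,
    CaseRecord,
    GazeRecording,
    LuminanceTrace,
    ROISet,
    ViewportState,
    ViewportTrace,
    make_roi,
    write_case_metadata,
    write_gaze_log,
    write_luminance_trace,
    write_roi_file,
    write_viewport_log,
)

#: Cycled case-category roster: all four categories appear first, then the
#: discordance-prone middle categories repeat (1:2:2:1 over a 12-case set).
DX_COMPOSITION = ("benign", "atypia", "dcis", "invasive", "atypia", "dcis")

#: Rating distributions over 1..6 for cases planted low / high difficulty.
RATING_P_LOW = (0.25, 0.30, 0.25, 0.12, 0.06, 0.02)
RATING_P_HIGH = (0.02, 0.08, 0.20, 0.28, 0.26, 0.16)

#: Rating threshold the generator uses to plant phasic trial types
#: (matches the pooled median of the rating model, ties to low).
PLANTED_MEDIAN = 3

SLIDE_SIZE = 40000.0       # slide px at 1x
ROI_HALF = 300.0           # ROI square half-side, slide px
ROI_REGION = (26000.0, 34000.0)   # ROI centres drawn here
FAR_REGION = (0.0, 12000.0)       # pre-event viewport origins drawn here

MIN_CENTER_DISTANCE = 150.0       # px between consecutive fixation centres


@dataclass
class SyntheticConfig:
    """Study-level generation parameters.

    Scales are anchored to the recorded task: ~13.3 px mean pupil
    diameter in eye-camera pixels, a 0.2 px tonic step per difficulty
    condition, a 0.5 px phasic amplitude, 30-90 s interpretations, and
    an 81% chance that a trial ever fixates a diagnostic ROI.
    """

    n_participants: int = 21
    cases_per_participant: int = 12
    sample_rate: float = 60.0
    trial_duration_s: tuple[float, float] = (30.0, 90.0)
    base_diameter_mean: float = 13.3
    base_diameter_sd: float = 0.3
    tonic_step: float = 0.2            # px per difficulty condition step
    phasic_amplitude: float = 0.5      # px, signed by trial type
    kernel_latency_to_peak_ms: float = 2000.0
    kernel_decay_ms: float = 3000.0
    blink_rate_per_min: float = 10.0
    blink_duration_ms: tuple[float, float] = (100.0, 400.0)
    p_droi_visit: float = 0.81
    p_agree_easy: float = 0.75
    p_agree_difficult: float = 0.45
    ar_phi: float = 0.95
    ar_sd: float = 0.05                # innovation sd, px
    luminance_bounds: tuple[float, float] = (0.35, 0.75)
    luminance_gain: float = 0.5        # px per unit intensity below 0.5
    rng_seed: int = 0

    def validate(self) -> "SyntheticConfig":
        if self.n_participants < 2 or self.cases_per_participant < 1:
            raise ValidationError("need >= 2 participants and >= 1 case each")
        if self.trial_duration_s[0] < 10 or \
                self.trial_duration_s[1] < self.trial_duration_s[0]:
            raise ValidationError("trial duration range invalid (min 10 s)")
        for name in ("base_diameter_sd", "blink_rate_per_min", "ar_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        for name in ("p_droi_visit", "p_agree_easy", "p_agree_difficult"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        lo, hi = self.luminance_bounds
        if not (0.0 < lo <= hi <= 1.0):
            raise ValidationError("luminance bounds must satisfy 0 < lo <= hi <= 1")
        if not 0.0 <= self.ar_phi < 1.0:
            raise ValidationError("AR(1) phi must lie in [0, 1)")
        return self


@dataclass
class TrialTruth:
    """Planted quantities for one generated trial."""

    participant_id: str
    case_id: str
    n_samples: int
    rating: int
    condition: str                  # A-D after the 6->4 collapse
    agreement: bool
    trial_type: str                 # planted 2x2 label
    visited_droi: bool
    event_sample: int | None        # scripted first-dROI-fixation onset
    kernel_amplitude: float
    blink_intervals: list[tuple[int, int]]
    fixation_onsets: list[int]


@dataclass
class TruthRecord:
    trials: list[TrialTruth] = field(default_factory=list)

    def by_trial(self) -> dict[tuple[str, str], TrialTruth]:
        return {(t.participant_id, t.case_id): t for t in self.trials}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump([asdict(t) for t in self.trials], fh, indent=1)


@dataclass
class Study:
    """A complete in-memory synthetic study."""

    config: SyntheticConfig
    metadata: list[CaseRecord]
    recordings: dict[tuple[str, str], GazeRecording]
    viewports: dict[tuple[str, str], ViewportTrace]
    luminance: dict[tuple[str, str], LuminanceTrace]
    rois: dict[str, ROISet]
    truth: TruthRecord


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def phasic_kernel(
    t_ms: np.ndarray | float,
    amplitude: float,
    latency_to_peak_ms: float = 2000.0,
    decay_ms: float = 3000.0,
) -> np.ndarray:
    """Smooth unimodal event-locked kernel.

    Zero at t = 0, raised-sine rise to ``amplitude`` at
    ``latency_to_peak_ms``, exponential decay after; zero for t < 0.
    Linear in amplitude, so a negative amplitude mirrors the curve.
    """
    t = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    rise = (t >= 0) & (t <= latency_to_peak_ms)
    out[rise] = np.sin(np.pi * t[rise] / (2.0 * latency_to_peak_ms)) ** 2
    fall = t > latency_to_peak_ms
    out[fall] = np.exp(-(t[fall] - latency_to_peak_ms) / decay_ms)
    return amplitude * out


def slide_to_screen(
    point_slide: tuple[float, float], state: ViewportState
) -> tuple[tuple[float, float], bool]:
    """Exact inverse of the screen-to-slide mapping.

    Returns the screen point and a visibility flag (False when the point
    falls outside the 1920 x 1080 viewport).
    """
    px, py = point_slide
    sx = (px - state.origin_x) * state.zoom
    sy = (py - state.origin_y) * state.zoom
    visible = 0.0 <= sx <= SCREEN_WIDTH and 0.0 <= sy <= SCREEN_HEIGHT
    return (sx, sy), visible


def _make_cases(cases_per_participant: int, rng: np.random.Generator):
    """Two case subsets mirroring the test-set composition: categories in
    1:2:2:1 proportion, half low / half high planted difficulty."""
    cases = []
    for subset in (0, 1):
        for k in range(cases_per_participant):
            category = DX_COMPOSITION[k % len(DX_COMPOSITION)]
            planted_high = k % 2 == 1
            cx = rng.uniform(*ROI_REGION)
            cy = rng.uniform(*ROI_REGION)
            cases.append({
                "case_id": f"C{subset}{k:02d}",
                "subset": subset,
                "category": category,
                "planted_high": planted_high,
                "roi_center": (cx, cy),
            })
    return cases


def _fixation_schedule(n: int, rng: np.random.Generator):
    """Alternating fixation/saccade segment lengths covering n samples.

    Returns a list of (kind, start, end) with kind 'F' or 'S'.
    """
    segs = []
    pos = 0
    while pos < n:
        flen = int(rng.integers(12, 31))
        end = min(pos + flen, n)
        segs.append(("F", pos, end))
        pos = end
        if pos >= n:
            break
        slen = int(rng.integers(2, 6))
        end = min(pos + slen, n)
        segs.append(("S", pos, end))
        pos = end
    return segs


def _draw_centers(n_fix: int, rng: np.random.Generator) -> np.ndarray:
    """Screen-pixel fixation centres with consecutive spacing >= 150 px."""
    lo = np.array([100.0, 100.0])
    hi = np.array([SCREEN_WIDTH - 100.0, SCREEN_HEIGHT - 100.0])
    centers = rng.uniform(lo, hi, size=(n_fix, 2))
    for i in range(1, n_fix):
        for _ in range(100):
            if np.hypot(*(centers[i] - centers[i - 1])) >= MIN_CENTER_DISTANCE:
                break
            centers[i] = rng.uniform(lo, hi)
    return centers


def _simulate_trial(cfg, rng, participant, case):
    """Generate one trial; returns (recording, viewport, luminance, truth,
    case_record)."""
    rate = cfg.sample_rate
    period = 1000.0 / rate
    duration = rng.uniform(*cfg.trial_duration_s)
    n = int(duration * rate)

    # --- planted design ----------------------------------------------------
    p_rating = RATING_P_HIGH if case["planted_high"] else RATING_P_LOW
    rating = int(rng.choice(np.arange(1, 7), p=p_rating))
    cond_idx = {1: 0, 2: 0, 3: 1, 4: 2, 5: 3, 6: 3}[rating]
    condition = "ABCD"[cond_idx]
    p_agree = cfg.p_agree_difficult if case["planted_high"] else cfg.p_agree_easy
    agree = bool(rng.random() < p_agree)
    difficult = rating > PLANTED_MEDIAN
    trial_type = ("difficult-" if difficult else "easy-") + \
        ("agree" if agree else "disagree")
    visited = bool(rng.random() < cfg.p_droi_visit)
    if visited and difficult:
        amplitude = cfg.phasic_amplitude if agree else -cfg.phasic_amplitude
    else:
        amplitude = 0.0

    # --- scanpath ----------------------------------------------------------
    segs = _fixation_schedule(n, rng)
    fix_segs = [s for s in segs if s[0] == "F"]
    centers = _draw_centers(len(fix_segs), rng)

    event_sample = None
    event_fix = None
    if visited:
        lo = max(int(0.2 * n), 66)
        hi = min(int(0.6 * n), n - 330)
        target = int(rng.integers(lo, hi))
        # fixation segment containing (or first after) the target sample
        for fi, (_, s, e) in enumerate(fix_segs):
            if e > target:
                event_fix = fi
                break
        # event fixation must leave a full post window
        while fix_segs[event_fix][1] + 300 > n and event_fix > 0:
            event_fix -= 1
        event_sample = fix_segs[event_fix][1]
        centers[event_fix] = (SCREEN_WIDTH / 2.0, SCREEN_HEIGHT / 2.0)
        # keep the neighbours clearly off the event cluster
        for nb in (event_fix - 1, event_fix + 1):
            if 0 <= nb < len(centers):
                while np.hypot(centers[nb, 0] - SCREEN_WIDTH / 2.0,
                               centers[nb, 1] - SCREEN_HEIGHT / 2.0) \
                        < MIN_CENTER_DISTANCE:
                    centers[nb] = rng.uniform(
                        [100.0, 100.0],
                        [SCREEN_WIDTH - 100.0, SCREEN_HEIGHT - 100.0],
                    )

    x = np.empty(n)
    y = np.empty(n)
    jitter = rng.normal(0.0, 1.0, size=(n, 2))
    for fi, (_, s, e) in enumerate(fix_segs):
        x[s:e] = centers[fi, 0] + jitter[s:e, 0]
        y[s:e] = centers[fi, 1] + jitter[s:e, 1]
    for kind, s, e in segs:
        if kind != "S":
            continue
        a = np.array([x[s - 1], y[s - 1]])
        nxt = np.array([x[e], y[e]]) if e < n else a
        # sweep stops at 60% of the way so the last saccade sample stays
        # clearly outside the landing cluster's dispersion window
        frac = 0.6 * np.arange(1, e - s + 1) / (e - s + 1)
        x[s:e] = a[0] + frac * (nxt[0] - a[0])
        y[s:e] = a[1] + frac * (nxt[1] - a[1])

    # --- viewport ----------------------------------------------------------
    states = []
    run_starts = [0]
    fi = 0
    while fi < len(fix_segs):
        fi += int(rng.integers(5, 11))
        if fi < len(fix_segs):
            run_starts.append(fi)
    if event_fix is not None:
        run_starts = sorted(set(
            s for s in run_starts
            if not (event_fix < s <= event_fix + 2)  # keep event run stable
        ) | {event_fix})
    for s in run_starts:
        t_start = fix_segs[s][1] * period if s > 0 else 0.0
        if event_fix is not None and s == event_fix:
            zoom = float(rng.uniform(4.0, 10.0))
            cx, cy = case["roi_center"]
            origin = (cx - SCREEN_WIDTH / 2.0 / zoom,
                      cy - SCREEN_HEIGHT / 2.0 / zoom)
        else:
            zoom = float(rng.uniform(1.0, 8.0))
            origin = (float(rng.uniform(*FAR_REGION)),
                      float(rng.uniform(*FAR_REGION)))
        states.append(ViewportState(t_start, zoom, origin[0], origin[1]))
    viewport = ViewportTrace(states)

    # --- luminance ---------------------------------------------------------
    n_frames = int(np.ceil(duration * 4))            # one frame per 250 ms
    lo, hi = cfg.luminance_bounds
    walk = np.cumsum(rng.normal(0.0, 0.01, size=n_frames))
    intensity = np.clip(rng.uniform(lo, hi) + walk, lo, hi)
    lum = LuminanceTrace(t=np.arange(n_frames) * 250.0, intensity=intensity)

    # --- diameter ----------------------------------------------------------
    t_ms = np.arange(n) * period
    innov = rng.normal(0.0, cfg.ar_sd, size=n)
    stat_sd = cfg.ar_sd / np.sqrt(1.0 - cfg.ar_phi ** 2) if cfg.ar_phi else cfg.ar_sd
    x0 = rng.normal(0.0, stat_sd)
    ar = lfilter([1.0], [1.0, -cfg.ar_phi], innov, zi=[cfg.ar_phi * x0])[0]
    d = participant["baseline"] + cfg.tonic_step * cond_idx + ar
    d = d + cfg.luminance_gain * (0.5 - lum.intensity_at(t_ms))
    if event_sample is not None and amplitude != 0.0:
        d = d + phasic_kernel(t_ms - event_sample * period, amplitude,
                              cfg.kernel_latency_to_peak_ms,
                              cfg.kernel_decay_ms)

    # --- blinks ------------------------------------------------------------
    valid = np.ones(n, dtype=bool)
    blink_intervals: list[tuple[int, int]] = []
    n_blinks = rng.poisson(cfg.blink_rate_per_min * duration / 60.0)
    if event_sample is not None:
        ev_lo = event_sample - 12
        ev_hi = fix_segs[event_fix][2] + 6
    for _ in range(int(n_blinks)):
        blen = int(round(rng.uniform(*cfg.blink_duration_ms) / period))
        blen = max(blen, 1)
        for _ in range(50):
            start = int(rng.integers(0, max(n - blen, 1)))
            if event_sample is None or not (start < ev_hi and
                                            start + blen > ev_lo):
                break
        else:
            continue
        valid[start:start + blen] = False
        blink_intervals.append((start, start + blen))
    d = d.copy()
    d[~valid] = 0.0
    x[~valid] = 0.0
    y[~valid] = 0.0

    pid, cid = participant["id"], case["case_id"]
    rec = GazeRecording(
        participant_id=pid, case_id=cid,
        t=t_ms, x=x, y=y, d=d, valid=valid, nominal_rate=rate,
    )
    truth = TrialTruth(
        participant_id=pid, case_id=cid, n_samples=n, rating=rating,
        condition=condition, agreement=agree, trial_type=trial_type,
        visited_droi=visited, event_sample=event_sample,
        kernel_amplitude=amplitude, blink_intervals=blink_intervals,
        fixation_onsets=[s for (_, s, _) in fix_segs],
    )
    others = [c for c in ("benign", "atypia", "dcis", "invasive")
              if c != case["category"]]
    case_record = CaseRecord(
        participant_id=pid, case_id=cid, expertise=participant["expertise"],
        consensus_dx=case["category"],
        participant_dx=case["category"] if agree else str(rng.choice(others)),
        difficulty_rating=rating,
    )
    return rec, viewport, lum, truth, case_record


# ---------------------------------------------------------------------------
# study-level generation
# ---------------------------------------------------------------------------

def simulate_study(config: SyntheticConfig | None = None) -> Study:
    """Generate a complete study in memory (no file I/O).

    Deterministic given ``config.rng_seed``; each trial uses a
    counter-keyed substream of the root seed.
    """
    cfg = (config or SyntheticConfig()).validate()
    root = np.random.default_rng([cfg.rng_seed, 0])
    cases = _make_cases(cfg.cases_per_participant, root)
    n_faculty = max(2, round(cfg.n_participants * 6 / 22))
    participants = []
    for i in range(cfg.n_participants):
        participants.append({
            "id": f"P{i:02d}",
            "expertise": "faculty" if i < n_faculty else "resident",
            "subset": i % 2,
            "baseline": float(root.normal(cfg.base_diameter_mean,
                                          cfg.base_diameter_sd)),
        })

    rois = {}
    for case in cases:
        cx, cy = case["roi_center"]
        rois[case["case_id"]] = ROISet(
            case_id=case["case_id"],
            rois=[make_roi("droi-1", [
                (cx - ROI_HALF, cy - ROI_HALF), (cx + ROI_HALF, cy - ROI_HALF),
                (cx + ROI_HALF, cy + ROI_HALF), (cx - ROI_HALF, cy + ROI_HALF),
            ])],
        )

    metadata = []
    recordings = {}
    viewports = {}
    luminance = {}
    truth = TruthRecord()
    counter = 0
    for p in participants:
        subset_cases = [c for c in cases if c["subset"] == p["subset"]]
        for case in subset_cases:
            counter += 1
            rng = np.random.default_rng([cfg.rng_seed, counter])
            rec, vp, lum, tt, cr = _simulate_trial(cfg, rng, p, case)
            key = (p["id"], case["case_id"])
            recordings[key] = rec
            viewports[key] = vp
            luminance[key] = lum
            truth.trials.append(tt)
            metadata.append(cr)

    return Study(config=cfg, metadata=metadata, recordings=recordings,
                 viewports=viewports, luminance=luminance, rois=rois,
                 truth=truth)


def generate_study(config: SyntheticConfig | None = None,
                   out_dir: str | Path = "study") -> tuple[Path, TruthRecord]:
    """Generate a study and write every artifact in readable formats.

    Layout::

        out_dir/
          metadata.csv
          truth.json
          rois/<case_id>.json
          gaze/<participant>_<case>.csv
          viewport/<participant>_<case>.csv
          luminance/<participant>_<case>.csv
    """
    study = simulate_study(config)
    out = Path(out_dir)
    for sub in ("gaze", "viewport", "luminance", "rois"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    write_case_metadata(study.metadata, out / "metadata.csv")
    study.truth.to_json(out / "truth.json")
    for case_id, roi_set in study.rois.items():
        write_roi_file(roi_set, out / "rois" / f"{case_id}.json")
    for (pid, cid), rec in study.recordings.items():
        stem = f"{pid}_{cid}"
        write_gaze_log(rec, out / "gaze" / f"{stem}.csv")
        write_viewport_log(study.viewports[(pid, cid)],
                           out / "viewport" / f"{stem}.csv")
        write_luminance_trace(study.luminance[(pid, cid)],
                              out / "luminance" / f"{stem}.csv")
    return out, study.truth
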