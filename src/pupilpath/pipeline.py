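"""End-to-end orchestration: preprocess -> fixations -> events -> tables
-> ANOVAs, with a manifest accounting for every trial.

A run consumes a study directory (as produced by
:func:`pupilpath.synthetic.generate_study`, or assembled from real
recordings in the same formats) and a YAML parameter file, and emits
tidy CSV tables, ANOVA JSONs and a ``manifest.json`` whose trial
dispositions partition the input:

* ``analyzed``            -- entered the phasic analysis;
* ``poor-quality``        -- overall null fraction above threshold, or no
                             valid samples at all;
* ``no-droi-fixation``    -- gaze never fixated a diagnostic ROI;
* ``insufficient-window`` -- the event sat too close to a recording edge;
* ``>50%-null``           -- too many nulls around the event.

Tonic and agreement analyses use every trial that survives the quality
stage; the phasic analysis additionally requires a usable event window.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fixation as fx
from . import phasic as ph
from . import stats as st
from . import tonic as tn
from .errors import InsufficientWindowError, UnrecoverableTrialError, ValidationError
from .gaze_io import (
    CaseRecord,
    read_case_metadata,
    read_gaze_log,
    read_luminance_trace,
    read_roi_file,
    read_viewport_log,
    write_trial_table,
)
from .preprocess import adjust_for_luminance, interpolate_nulls
from .synthetic import Study, SyntheticConfig
from .tables import impute_condition_means


@dataclass
class PipelineParams:
    """All analysis thresholds, with task defaults."""

    dispersion_px: float = 41.0
    min_fixation_ms: float = 100.0
    null_exclusion_threshold: float = 0.5   # phasic window rule (strict >)
    max_trial_null_fraction: float = 0.5    # whole-trial quality rule
    luminance_adjust: bool = False
    luminance_mode: str = "multiply"
    median_ties: str = "low"
    gg_correction: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineParams":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class RunManifest:
    """Per-trial dispositions plus stage counts; dispositions partition
    the input trials and stage counts are mutually consistent."""

    params: dict
    trials: list[dict] = field(default_factory=list)

    DISPOSITIONS = ("analyzed", "poor-quality", "no-droi-fixation",
                    "insufficient-window", ">50%-null")

    def add(self, participant_id: str, case_id: str, disposition: str,
            detail: str = "") -> None:
        if disposition not in self.DISPOSITIONS:
            raise ValidationError(f"unknown disposition {disposition!r}")
        self.trials.append({
            "participant_id": participant_id,
            "case_id": case_id,
            "disposition": disposition,
            "detail": detail,
        })

    def counts(self) -> dict[str, int]:
        c = {d: 0 for d in self.DISPOSITIONS}
        for t in self.trials:
            c[t["disposition"]] += 1
        return c

    @property
    def stage_counts(self) -> dict[str, int]:
        c = self.counts()
        n_input = len(self.trials)
        n_quality = n_input - c["poor-quality"]
        n_event = n_quality - c["no-droi-fixation"]
        n_window = n_event - c["insufficient-window"]
        n_phasic = n_window - c[">50%-null"]
        return {
            "input": n_input,
            "after_quality": n_quality,
            "with_droi_event": n_event,
            "with_full_window": n_window,
            "phasic_analyzed": n_phasic,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"params": self.params, "stage_counts": self.stage_counts,
                       "counts": self.counts(), "trials": self.trials},
                      fh, indent=1)


def exclusion_report(manifest: RunManifest) -> dict:
    """Counts and percentages per exclusion reason.

    Percentages are of all input trials and sum to 100.  The dROI-visit
    percentage counts every trial that produced an event (analyzed or
    dropped later for window nulls) out of all input trials.
    """
    counts = manifest.counts()
    n = len(manifest.trials)
    pct = {d: (100.0 * c / n if n else 0.0) for d, c in counts.items()}
    with_event = counts["analyzed"] + counts[">50%-null"] \
        + counts["insufficient-window"]
    report = {
        "n_input": n,
        "counts": counts,
        "percentages": pct,
        "n_after_quality": n - counts["poor-quality"],
        "n_phasic_analyzed": counts["analyzed"],
        "percent_with_droi_event": 100.0 * with_event / n if n else 0.0,
    }
    lines = [f"{n} trials in"]
    for d in manifest.DISPOSITIONS:
        lines.append(f"  {d:>20}: {counts[d]:4d} ({pct[d]:5.1f}%)")
    lines.append(f"  after quality screen: {report['n_after_quality']}")
    lines.append(
        f"  fixated a dROI on {with_event} trials "
        f"({report['percent_with_droi_event']:.1f}% of trials)"
    )
    report["text"] = "\n".join(lines)
    return report


# ---------------------------------------------------------------------------
# study loading
# ---------------------------------------------------------------------------

def load_study(study_dir: str | Path) -> Study:
    """Read a study directory back into the in-memory representation."""
    root = Path(study_dir)
    metadata = read_case_metadata(root / "metadata.csv")
    recordings = {}
    viewports = {}
    luminance = {}
    for rec_meta in metadata:
        key = (rec_meta.participant_id, rec_meta.case_id)
        stem = f"{rec_meta.participant_id}_{rec_meta.case_id}"
        recordings[key] = read_gaze_log(
            root / "gaze" / f"{stem}.csv",
            participant_id=rec_meta.participant_id,
            case_id=rec_meta.case_id,
        )
        viewports[key] = read_viewport_log(root / "viewport" / f"{stem}.csv")
        lum_path = root / "luminance" / f"{stem}.csv"
        if lum_path.exists():
            luminance[key] = read_luminance_trace(lum_path)
    rois = {}
    for roi_path in sorted((root / "rois").glob("*.json")):
        rs = read_roi_file(roi_path)
        rois[rs.case_id] = rs
    from .synthetic import TruthRecord
    return Study(config=SyntheticConfig(), metadata=metadata,
                 recordings=recordings, viewports=viewports,
                 luminance=luminance, rois=rois, truth=TruthRecord())


# ---------------------------------------------------------------------------
# analysis stages
# ---------------------------------------------------------------------------

@dataclass
class StudyResults:
    manifest: RunManifest
    tonic_table: "pd.DataFrame | None" = None
    tonic_anova: st.AnovaResult | None = None
    phasic_table: "pd.DataFrame | None" = None
    phasic_anova: st.AnovaResult | None = None
    agreement_table: "pd.DataFrame | None" = None
    agreement_anova: st.AnovaResult | None = None
    agreement_pairwise: "pd.DataFrame | None" = None
    phasic_mean_traces: "pd.DataFrame | None" = None
    difficulty_median: float | None = None
    phasic_traces: list = field(default_factory=list)
    events: dict = field(default_factory=dict)


def _clean_trial(study: Study, meta: CaseRecord, params: PipelineParams):
    key = (meta.participant_id, meta.case_id)
    rec = study.recordings[key]
    clean = interpolate_nulls(rec)
    if params.luminance_adjust:
        lum = study.luminance.get(key)
        if lum is None:
            raise ValidationError(f"{key}: luminance adjustment requested "
                                  "but no trace available")
        clean = adjust_for_luminance(clean, lum, mode=params.luminance_mode)
    return clean


def tonic_analysis(study: Study, params: PipelineParams | None = None,
                   metadata: list[CaseRecord] | None = None):
    """Tonic pipeline: clean -> normalize -> bin -> impute -> RM-ANOVA.

    Returns ``(cell_table, anova, skipped)`` where ``skipped`` lists
    trials dropped for quality.
    """
    params = params or PipelineParams()
    metadata = metadata if metadata is not None else study.metadata
    profiles = []
    skipped = []
    for meta in metadata:
        try:
            clean = _clean_trial(study, meta, params)
        except UnrecoverableTrialError:
            skipped.append((meta.participant_id, meta.case_id, "no valid samples"))
            continue
        if clean.null_fraction > params.max_trial_null_fraction:
            skipped.append((meta.participant_id, meta.case_id,
                            f"null fraction {clean.null_fraction:.2f}"))
            continue
        profiles.append(tn.tonic_profile(clean, meta.difficulty_rating))
    table = impute_condition_means(tn.build_tonic_table(profiles))
    anova = st.rm_anova(table.values, ("difficulty", "time"),
                        gg=params.gg_correction)
    return table, anova, skipped


def analyze_study(study: Study,
                  params: PipelineParams | None = None) -> StudyResults:
    """Run the complete analysis on an in-memory study."""
    params = params or PipelineParams()
    manifest = RunManifest(params=asdict(params))
    results = StudyResults(manifest=manifest)

    # ---- stage 1: quality screen + cleaning -------------------------------
    cleans: dict[tuple[str, str], object] = {}
    survivors: list[CaseRecord] = []
    for meta in study.metadata:
        key = (meta.participant_id, meta.case_id)
        try:
            clean = _clean_trial(study, meta, params)
        except UnrecoverableTrialError:
            manifest.add(*key, "poor-quality", "no valid samples")
            continue
        if clean.null_fraction > params.max_trial_null_fraction:
            manifest.add(*key, "poor-quality",
                         f"null fraction {clean.null_fraction:.2f}")
            continue
        cleans[key] = clean
        survivors.append(meta)

    # ---- tonic ------------------------------------------------------------
    profiles = [tn.tonic_profile(cleans[(m.participant_id, m.case_id)],
                                 m.difficulty_rating)
                for m in survivors]
    tonic_table = impute_condition_means(tn.build_tonic_table(profiles))
    results.tonic_table = tonic_table.to_frame()
    results.tonic_anova = st.rm_anova(tonic_table.values,
                                      ("difficulty", "time"),
                                      gg=params.gg_correction)

    # ---- events + phasic windows -------------------------------------------
    windows: list[tuple[CaseRecord, ph.PhasicTrace]] = []
    for meta in survivors:
        key = (meta.participant_id, meta.case_id)
        clean = cleans[key]
        fixations = fx.detect_fixations(clean, params.dispersion_px,
                                        params.min_fixation_ms)
        event = fx.first_droi_fixation(
            fixations, study.rois[meta.case_id], study.viewports[key],
            participant_id=meta.participant_id, case_id=meta.case_id,
        )
        if event is None:
            manifest.add(*key, "no-droi-fixation")
            continue
        results.events[key] = event
        try:
            trace = ph.extract_event_window(clean, event.event_index)
        except InsufficientWindowError as exc:
            manifest.add(*key, "insufficient-window", str(exc))
            continue
        if not ph.exclude_high_null(trace, params.null_exclusion_threshold):
            manifest.add(*key, ">50%-null",
                         f"window null fraction "
                         f"{trace.null_fraction_window:.2f}")
            continue
        manifest.add(*key, "analyzed")
        windows.append((meta, trace))

    if windows:
        med = ph.difficulty_median([m.difficulty_rating for m, _ in windows])
        results.difficulty_median = med
        for meta, trace in windows:
            trace.trial_type = ph.classify_trial(meta, med,
                                                 ties=params.median_ties)
        results.phasic_traces = [tr for _, tr in windows]
        phasic_table = impute_condition_means(
            ph.build_phasic_table(results.phasic_traces)
        )
        results.phasic_table = phasic_table.to_frame()
        results.phasic_anova = st.rm_anova(phasic_table.values,
                                           ("trial type", "time"),
                                           gg=params.gg_correction)
        rows = {}
        for ttype in ph.TRIAL_TYPES:
            traces = [tr.relative for tr in results.phasic_traces
                      if tr.trial_type == ttype]
            if traces:
                rows[ttype] = np.mean(traces, axis=0)
        frame = pd.DataFrame(rows)
        frame.insert(0, "t_ms", np.arange(ph.POST_SAMPLES) * 1000.0 / 60.0)
        results.phasic_mean_traces = frame

    # ---- agreement --------------------------------------------------------
    results.agreement_table, results.agreement_anova, \
        results.agreement_pairwise = agreement_analysis(survivors)
    return results


def agreement_analysis(metadata: list[CaseRecord]):
    """Mixed ANOVA of agreement rates: diagnostic category (within) x
    expertise (between), plus pairwise paired t-tests across categories."""
    from .gaze_io import DX_CATEGORIES
    df = pd.DataFrame([
        (m.participant_id, m.expertise, m.consensus_dx, float(m.agreement))
        for m in metadata
    ], columns=["participant_id", "expertise", "category", "agree"])
    cell = df.groupby(["participant_id", "category"])["agree"].mean().unstack()
    cell = cell.reindex(columns=[c for c in DX_CATEGORIES
                                 if c in cell.columns])
    # a participant with no analyzed trial of a category gets the
    # category mean (condition-mean imputation, as in the cell tables)
    cell = cell.fillna(cell.mean(axis=0))
    groups = df.drop_duplicates("participant_id").set_index(
        "participant_id")["expertise"]
    groups = groups.loc[cell.index].tolist()
    anova = st.mixed_anova(cell.to_numpy(), groups,
                           within_name="category", between_name="expertise")
    pairwise = st.pairwise_paired_t(cell.to_numpy(), list(cell.columns))
    tidy = cell.reset_index().melt(id_vars="participant_id",
                                   var_name="category", value_name="agreement")
    return tidy, anova, pairwise


# ---------------------------------------------------------------------------
# file-level entry point
# ---------------------------------------------------------------------------

def run_study(config_path: str | Path) -> StudyResults:
    """Run a complete study from a YAML config.

    Config keys: ``study_dir`` (required), ``out_dir`` (required), plus
    any :class:`PipelineParams` field.
    """
    with open(config_path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    for key in ("study_dir", "out_dir"):
        if key not in cfg:
            raise ValidationError(f"config missing required key {key!r}")
    params = PipelineParams.from_dict(cfg)
    study = load_study(cfg["study_dir"])
    results = analyze_study(study, params)

    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    results.manifest.to_json(out / "manifest.json")
    if results.tonic_table is not None:
        write_trial_table(results.tonic_table, out / "tonic_table.csv")
        results.tonic_anova.to_json(out / "anova_tonic.json")
    if results.phasic_table is not None:
        write_trial_table(results.phasic_table, out / "phasic_bins.csv")
        results.phasic_anova.to_json(out / "anova_phasic.json")
        write_trial_table(results.phasic_mean_traces,
                          out / "phasic_mean_traces.csv")
    if results.agreement_table is not None:
        write_trial_table(results.agreement_table, out / "agreement.csv")
        results.agreement_anova.to_json(out / "anova_agreement.json")
        write_trial_table(results.agreement_pairwise,
                          out / "agreement_pairwise.csv")
    report = exclusion_report(results.manifest)
    with open(out / "exclusions.txt", "w", encoding="utf-8") as fh:
        fh.write(report["text"] + "\n")
    return results
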