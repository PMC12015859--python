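"""End-to-end orchestration: simulate -> preprocess -> SSVEP + ERP + behavior.

The cohort helpers here are the workhorses for validation studies (parameter
recovery, null calibration): they simulate subjects from a trial schedule and
a ground truth, push each one through the full preprocessing chain and return
analysis-ready quantities.  ``run_end_to_end`` ties everything together from
a :class:`~stereoattn.config.RunConfig`, writing intermediates and a
consolidated report with checksums.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import classify_responses, summarize_behavior
from .config import RunConfig
from .design import (TrialSchedule, generate_trial_schedule,
                     schedule_to_events_frame)
from .erp import (ERP_EPOCH_MS, ErpResult, baseline_correct, erp_windows,
                  lowpass_for_erp, select_correct_response_events)
from .io import sha256_of, write_edf, write_events_tsv, write_json
from .montage import Montage, standard_montage
from .preprocess import PreprocParams, preprocess_epochs, remove_dc
from .simulate import ContinuousRecording, GroundTruth, generate_subject
from .ssvep import ssvep_inference, subject_ssvep_courses

__all__ = ["subject_seed_streams", "ssvep_subject_course",
            "ssvep_cohort", "erp_cohort", "behavior_cohort", "run_end_to_end"]

logger = logging.getLogger(__name__)

SSVEP_EPOCH_MS = (-1000.0, 2000.0)


def subject_seed_streams(seed: int, n_subjects: int) -> list[np.random.Generator]:
    """Independent per-subject random streams derived from one global seed."""
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n_subjects)]


def _event_free_cue_anchors(rec: ContinuousRecording, schedule: TrialSchedule
                            ) -> tuple[np.ndarray, pd.DataFrame]:
    cue_samples = rec.marker_samples("cue:")
    cues = [lab.split(":")[1] for _, lab in rec.markers if lab.startswith("cue:")]
    event_free = np.array([len(t.events) == 0 for t in schedule.trials])
    anchors = cue_samples[event_free]
    labels = pd.DataFrame({"cue": np.array(cues)[event_free]})
    return anchors, labels


def ssvep_subject_course(rec: ContinuousRecording, schedule: TrialSchedule,
                         gt: GroundTruth, params: PreprocParams | None = None,
                         return_epochs: bool = False):
    """Attended/ignored percent-change courses for one subject.

    Cue-locked epochs (-1000 to 2000 ms) from event-free trials run through
    the full preprocessing chain before Gabor filtering.  Returns
    ``(attended, ignored, times_ms)``, plus the preprocessed epoch set when
    ``return_epochs`` is true.
    """
    remove_dc(rec)
    anchors, labels = _event_free_cue_anchors(rec, schedule)
    epochs = preprocess_epochs(rec, anchors, SSVEP_EPOCH_MS, "cue",
                               labels=labels, params=params)
    att, ign = subject_ssvep_courses(epochs, plane_of_freq=gt.plane_of_freq)
    if return_epochs:
        return att, ign, epochs.times_ms, epochs
    return att, ign, epochs.times_ms


def ssvep_cohort(n_subjects: int, schedule: TrialSchedule, gt: GroundTruth,
                 seed: int, params: PreprocParams | None = None,
                 montage: Montage | None = None
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate and analyze a cohort; returns (attended, ignored, times).

    ``attended`` and ``ignored`` are subjects x timepoints percent-change
    arrays ready for :func:`stereoattn.ssvep.ssvep_inference`.
    """
    montage = montage or standard_montage()
    att_all, ign_all, times = [], [], None
    for rng in subject_seed_streams(seed, n_subjects):
        rec, _, _ = generate_subject(schedule, gt, montage, seed=rng)
        att, ign, times = ssvep_subject_course(rec, schedule, gt, params)
        att_all.append(att)
        ign_all.append(ign)
    return np.array(att_all), np.array(ign_all), times


def erp_subject_epochs(rec: ContinuousRecording, schedule: TrialSchedule,
                       presses: list[float],
                       params: PreprocParams | None = None):
    """Event-locked, baseline-corrected CSD epochs for correct events only."""
    remove_dc(rec)
    filtered = lowpass_for_erp(rec)
    events, press_tbl = classify_responses(schedule, presses)
    # anchor on the recording's own event markers (sample-accurate); the
    # classified table is chronological, matching marker order
    ev_samples = rec.marker_samples("event:")
    if len(ev_samples) != len(events):
        raise ValueError("event markers do not match the classified schedule")
    events = events.assign(sample=ev_samples)
    correct = select_correct_response_events(events)
    anchors = correct["sample"].to_numpy()
    labels = correct[["attended", "plane", "cue"]].reset_index(drop=True)
    epochs = preprocess_epochs(filtered, anchors, ERP_EPOCH_MS, "event",
                               labels=labels, params=params)
    return baseline_correct(epochs)


def erp_cohort(n_subjects: int, schedule: TrialSchedule, gt: GroundTruth,
               seed: int, params: PreprocParams | None = None,
               montage: Montage | None = None) -> ErpResult:
    """Simulate a cohort with motion events and run the ERP window analysis."""
    montage = montage or standard_montage()
    subject_epochs = []
    for rng in subject_seed_streams(seed, n_subjects):
        rec, _, presses = generate_subject(schedule, gt, montage, seed=rng)
        subject_epochs.append(erp_subject_epochs(rec, schedule, presses, params))
    return erp_windows(subject_epochs)


def behavior_cohort(n_subjects: int, schedule: TrialSchedule, gt: GroundTruth,
                    seed: int) -> list:
    """Behavior-only cohort (no EEG synthesis): classified summaries."""
    from .simulate import simulate_presses

    out = []
    for rng in subject_seed_streams(seed, n_subjects):
        presses = simulate_presses(schedule, gt.p_hit, gt.p_fa, gt.rt_shift_ms,
                                   gt.rt_median_ms, gt.rt_sigma, seed=rng)
        events, press_tbl = classify_responses(schedule, presses)
        out.append(summarize_behavior(events, press_tbl))
    return out


def _status_counts(epochs) -> dict:
    vals, counts = np.unique(epochs.status, return_counts=True)
    return {str(v): int(c) for v, c in zip(vals, counts)}


def run_end_to_end(config: RunConfig) -> dict:
    """Full pipeline from a config; returns the consolidated report.

    Writes the events TSV, per-subject summaries, group results and a report
    JSON (with SHA-256 checksums of every written file) into
    ``config.out_dir``.  Identical configs produce identical reports.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    schedule = generate_trial_schedule(config.n_trials, config.composition,
                                       config.timing, seed=config.seed)
    events_path = write_events_tsv(out / "events.tsv",
                                   schedule_to_events_frame(schedule))
    written["events.tsv"] = sha256_of(events_path)

    montage = standard_montage()
    gt = config.ground_truth
    att_all, ign_all, times = [], [], None
    subject_erp = []
    behav_rows = []
    rejections: list[dict] = []
    for i, rng in enumerate(subject_seed_streams(config.seed, config.n_subjects)):
        logger.info("simulating subject %d", i)
        rec, truth, presses = generate_subject(schedule, gt, montage,
                                               rate=config.rate, seed=rng)
        if config.write_raw:
            p = write_edf(out / f"sub-{i:02d}_eeg.edf", rec)
            written[p.name] = sha256_of(p)
        if any(len(t.events) == 0 for t in schedule.trials):
            att, ign, times, ssvep_ep = ssvep_subject_course(
                rec.copy(), schedule, gt, config.preproc, return_epochs=True)
            att_all.append(att)
            ign_all.append(ign)
            rejections.append({"subject": i, "stage": "ssvep",
                               **_status_counts(ssvep_ep)})
        if schedule.n_events:
            erp_ep = erp_subject_epochs(rec, schedule, presses, config.preproc)
            subject_erp.append(erp_ep)
            rejections.append({"subject": i, "stage": "erp",
                               **_status_counts(erp_ep)})
            events, press_tbl = classify_responses(schedule, presses)
            behav_rows.append(summarize_behavior(events, press_tbl).to_dict())

    report: dict = {"config_seed": config.seed,
                    "n_subjects": config.n_subjects,
                    "n_trials": config.n_trials}
    if att_all:
        res = ssvep_inference(np.array(att_all), np.array(ign_all), times)
        course_path = out / "ssvep_courses.csv"
        frames = []
        for cond, arr in (("attended", att_all), ("ignored", ign_all)):
            for s, course in enumerate(arr):
                frames.append(pd.DataFrame({
                    "subject": s, "condition": cond,
                    "time_ms": times, "pct_change": course}))
        pd.concat(frames, ignore_index=True).to_csv(course_path, index=False)
        written[course_path.name] = sha256_of(course_path)
        report["ssvep"] = {
            "window_ms": list(res.window_ms),
            "attended_window_mean_pct": float(res.window_means[:, 0].mean()),
            "ignored_window_mean_pct": float(res.window_means[:, 1].mean()),
            "between_t": res.window_test.statistic,
            "between_p": res.window_test.p,
            "between_bf10": res.window_test.bf10,
        }
    if subject_erp:
        erp_res = erp_windows(subject_erp)
        report["erp"] = {
            comp: {"attended_mean": float(v[:, 0].mean()),
                   "ignored_mean": float(v[:, 1].mean()),
                   "t": erp_res.tests[comp].statistic,
                   "p": erp_res.tests[comp].p,
                   "bf10": erp_res.tests[comp].bf10}
            for comp, v in erp_res.window_means.items()}
    if behav_rows:
        behav_path = out / "behavior.csv"
        pd.DataFrame(behav_rows).to_csv(behav_path, index=False)
        written[behav_path.name] = sha256_of(behav_path)
        df = pd.DataFrame(behav_rows)
        report["behavior"] = {
            "hit_rate_pct": float(df["hit_rate_pct"].mean()),
            "fa_rate_pct": float(df["fa_rate_pct"].mean()),
            "dprime": float(df["dprime"].mean()),
            "mean_rt_ms": float(df["mean_rt_ms"].mean()),
        }
    if rejections:
        rej_path = out / "rejection_summary.csv"
        pd.DataFrame(rejections).fillna(0).to_csv(rej_path, index=False)
        written[rej_path.name] = sha256_of(rej_path)
        report["rejections"] = rejections
    report["files"] = written
    write_json(out / "report.json", report)
    return report
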