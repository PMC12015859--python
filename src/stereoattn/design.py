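"""Stimulus geometry and trial scheduling for the depth-attention experiment.

Two superimposed random-dot kinematograms (RDKs) are frequency-tagged (15 and
18 Hz) and displaced symmetrically in front of / behind the fixation plane via
binocular disparity.  This module computes the viewing geometry (visual angles,
disparities), builds frame-interpolated flicker sequences for the tagged
stimuli, and generates randomized trial/event schedules with the composition
and timing constraints of the task: coherent-motion events start no earlier
than 200 ms after the attention cue and are separated by a configurable
minimum gap inside a 2000 ms post-cue window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StimulusSpec",
    "ViewingGeometry",
    "ScheduleTiming",
    "Trial",
    "TrialSchedule",
    "visual_angle_deg",
    "binocular_disparity_deg",
    "coherent_motion_displacement_deg",
    "flicker_frame_sequence",
    "generate_trial_schedule",
    "validate_schedule",
    "schedule_to_events_frame",
    "schedule_from_events_frame",
]

PLANES = ("front", "back")


@dataclass(frozen=True)
class StimulusSpec:
    """Physical parameters of the two flickering RDKs.

    Defaults are the published stimulus: 6.92° diameter, 80 dots of edge
    0.334° moving at 3.80°/s, 32 coherently moving dots per 300 ms event,
    tagging frequencies 15 and 18 Hz on a 240 Hz per-eye refresh.
    """

    rdk_diameter_deg: float = 6.92
    dot_edge_deg: float = 0.334
    n_dots: int = 80
    dot_speed_deg_s: float = 3.80
    coherent_fraction: int = 32
    event_duration_ms: float = 300.0
    flicker_freqs_hz: tuple[float, float] = (15.0, 18.0)
    refresh_hz_per_eye: float = 240.0

    def __post_init__(self) -> None:
        vals = (self.rdk_diameter_deg, self.dot_edge_deg, self.n_dots,
                self.dot_speed_deg_s, self.coherent_fraction,
                self.event_duration_ms, self.refresh_hz_per_eye)
        if any(v <= 0 for v in vals):
            raise ValueError("all stimulus parameters must be positive")
        if self.coherent_fraction > self.n_dots:
            raise ValueError("coherent_fraction cannot exceed n_dots")
        f1, f2 = self.flicker_freqs_hz
        if f1 == f2:
            raise ValueError("flicker frequencies must be distinct")
        if max(f1, f2) >= self.refresh_hz_per_eye / 2:
            raise ValueError("flicker frequencies must lie below the per-eye Nyquist rate")


@dataclass(frozen=True)
class ViewingGeometry:
    """Stereo viewing geometry.

    ``pupil_nose_mm`` is the pupil-to-nose distance (half the interocular
    distance), ``viewing_distance_cm`` the distance to the fixation plane and
    ``depth_offset_cm`` the symmetric displacement of the two stimulus planes
    (crossed disparity in front, uncrossed behind).
    """

    pupil_nose_mm: float = 31.9
    viewing_distance_cm: float = 120.0
    depth_offset_cm: float = 10.0

    def __post_init__(self) -> None:
        if not (20.0 <= self.pupil_nose_mm <= 50.0):
            raise ValueError("pupil_nose_mm outside the plausible 20-50 mm range")
        if not (self.viewing_distance_cm > self.depth_offset_cm > 0):
            raise ValueError("require viewing_distance > depth_offset > 0")

    @property
    def ipd_mm(self) -> float:
        """Interocular distance (twice the pupil-nose distance)."""
        return 2.0 * self.pupil_nose_mm


def visual_angle_deg(physical_size_cm: float, distance_cm: float) -> float:
    """Visual angle subtended by an object of ``physical_size_cm`` at ``distance_cm``.

    Returns ``2 * atan(size / (2 * distance))`` in degrees.
    """
    if distance_cm <= 0:
        raise ValueError("viewing distance must be positive")
    if physical_size_cm < 0:
        raise ValueError("size must be non-negative")
    return math.degrees(2.0 * math.atan(physical_size_cm / (2.0 * distance_cm)))


def binocular_disparity_deg(geometry: ViewingGeometry, plane: str = "front",
                            mode: str = "small_angle") -> float:
    """Absolute binocular disparity of a stimulus plane relative to fixation.

    ``small_angle`` uses the thin-triangle approximation ``IPD * dd / D**2``
    (identical magnitude for crossed and uncrossed planes); ``exact_vergence``
    returns the absolute difference of the two vergence angles
    ``|2*atan(IPD/2 / D_plane) - 2*atan(IPD/2 / D_fix)|``, which is slightly
    larger for the near (crossed) plane.
    """
    if plane not in PLANES:
        raise ValueError(f"plane must be one of {PLANES}")
    ipd_cm = geometry.ipd_mm / 10.0
    d_fix = geometry.viewing_distance_cm
    dd = geometry.depth_offset_cm
    if mode == "small_angle":
        return math.degrees(ipd_cm * dd / d_fix**2)
    if mode == "exact_vergence":
        d_plane = d_fix - dd if plane == "front" else d_fix + dd
        verg = lambda d: 2.0 * math.atan(ipd_cm / 2.0 / d)
        return abs(math.degrees(verg(d_plane) - verg(d_fix)))
    raise ValueError(f"unknown disparity mode {mode!r}")


def coherent_motion_displacement_deg(speed_deg_s: float, duration_ms: float) -> float:
    """Total displacement of coherently moving dots over one event."""
    if speed_deg_s < 0 or duration_ms < 0:
        raise ValueError("speed and duration must be non-negative")
    return speed_deg_s * duration_ms / 1000.0


def flicker_frame_sequence(freq_hz: float, refresh_hz_per_eye: float,
                           n_frames: int) -> np.ndarray:
    """Per-frame intensity for an on-off flicker via temporal frame interpolation.

    Each frame's intensity is the fraction of its duration during which an
    ideal 50 %-duty square wave at ``freq_hz`` is on.  When the refresh rate is
    an integer multiple of the flicker frequency the sequence is binary; for
    incommensurate frequencies (e.g. 18 Hz at 240 Hz) boundary frames take
    fractional values, which keeps the spectral peak exactly at ``freq_hz``.
    """
    if not (0 < freq_hz < refresh_hz_per_eye / 2):
        raise ValueError("freq_hz must lie in (0, refresh/2)")
    if n_frames < 0:
        raise ValueError("n_frames must be non-negative")
    if n_frames == 0:
        return np.zeros(0)
    edges = np.arange(n_frames + 1) / refresh_hz_per_eye
    # integral of the on-off square wave up to time t, in units of "on" time
    period = 1.0 / freq_hz

    def on_time(t: np.ndarray) -> np.ndarray:
        cycles, frac = np.divmod(t, period)
        return cycles * (period / 2.0) + np.minimum(frac, period / 2.0)

    on = np.diff(on_time(edges))
    return on * refresh_hz_per_eye


# --------------------------------------------------------------------------
# trial schedule
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScheduleTiming:
    """Timing constraints of the trial structure (milliseconds).

    ``min_event_gap_ms`` is the offset-to-onset delay between successive
    coherent-motion events; with 300 ms events the default corresponds to an
    onset-to-onset separation of at least 1100 ms.
    """

    pre_cue_ms: float = 1300.0
    post_cue_ms: float = 2000.0
    iti_ms: float = 1000.0
    event_min_onset_ms: float = 200.0
    event_duration_ms: float = 300.0
    min_event_gap_ms: float = 800.0

    @property
    def min_onset_to_onset_ms(self) -> float:
        return self.min_event_gap_ms + self.event_duration_ms

    @property
    def trial_ms(self) -> float:
        return self.pre_cue_ms + self.post_cue_ms + self.iti_ms


@dataclass(frozen=True)
class Trial:
    index: int
    block: int
    cue: str                                  # attended plane: front / back
    events: tuple[tuple[float, str], ...]     # (onset ms after cue, plane)


@dataclass
class TrialSchedule:
    """Per-trial cue conditions and coherent-motion event placements."""

    trials: list[Trial]
    timing: ScheduleTiming = field(default_factory=ScheduleTiming)
    n_blocks: int = 8

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_events(self) -> int:
        return sum(len(t.events) for t in self.trials)

    def event_records(self) -> list[dict]:
        """Flat per-event records with attended/ignored labels."""
        recs = []
        for t in self.trials:
            for onset, plane in t.events:
                recs.append({
                    "trial": t.index, "block": t.block, "cue": t.cue,
                    "onset_ms": onset, "plane": plane,
                    "attended": plane == t.cue,
                })
        return recs


def generate_trial_schedule(n_trials: int = 960,
                            composition: tuple[int, int, int] = (480, 240, 240),
                            timing: ScheduleTiming | None = None,
                            n_blocks: int = 8,
                            seed: int | np.random.Generator = 0) -> TrialSchedule:
    """Generate a randomized trial schedule.

    ``composition = (n0, n1, n2)`` gives the number of trials with zero, one
    and two coherent-motion events (defaults: 480/240/240 of 960).  Cue
    conditions are balanced across trials, event planes are drawn with equal
    probability, and event onsets are sampled uniformly subject to the timing
    constraints (start >= ``event_min_onset_ms``, events end inside the
    post-cue window, successive events separated by the configured gap).
    """
    timing = timing or ScheduleTiming()
    n0, n1, n2 = composition
    if n0 + n1 + n2 != n_trials:
        raise ValueError("composition must sum to n_trials")
    if n_trials % n_blocks:
        raise ValueError("n_trials must divide evenly into blocks")
    lo = timing.event_min_onset_ms
    hi = timing.post_cue_ms - timing.event_duration_ms
    if hi < lo:
        raise ValueError("no room for a single event in the post-cue window")
    if n2 and hi - lo < timing.min_onset_to_onset_ms:
        raise ValueError("two events cannot fit in the post-cue window")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_events_per_trial = np.repeat([0, 1, 2], [n0, n1, n2])
    rng.shuffle(n_events_per_trial)
    cues = np.tile(["front", "back"], n_trials // 2 + 1)[:n_trials]
    rng.shuffle(cues)

    per_block = n_trials // n_blocks
    trials = []
    for i in range(n_trials):
        k = int(n_events_per_trial[i])
        if k == 0:
            events: tuple = ()
        elif k == 1:
            onset = rng.uniform(lo, hi)
            events = ((onset, rng.choice(PLANES)),)
        else:
            # rejection-free: draw first onset, then second beyond the gap
            gap = timing.min_onset_to_onset_ms
            o1 = rng.uniform(lo, hi - gap)
            o2 = rng.uniform(o1 + gap, hi)
            events = ((o1, rng.choice(PLANES)), (o2, rng.choice(PLANES)))
        trials.append(Trial(index=i, block=i // per_block, cue=str(cues[i]),
                            events=events))
    sched = TrialSchedule(trials=trials, timing=timing, n_blocks=n_blocks)
    validate_schedule(sched, composition)
    return sched


def validate_schedule(schedule: TrialSchedule,
                      composition: tuple[int, int, int] | None = None) -> None:
    """Re-check every schedule invariant; raises ``ValueError`` on violation."""
    t = schedule.timing
    counts = [0, 0, 0]
    for trial in schedule.trials:
        if trial.cue not in PLANES:
            raise ValueError(f"trial {trial.index}: bad cue {trial.cue!r}")
        k = len(trial.events)
        if k > 2:
            raise ValueError(f"trial {trial.index}: more than two events")
        counts[k] += 1
        onsets = [o for o, _ in trial.events]
        for onset, plane in trial.events:
            if plane not in PLANES:
                raise ValueError(f"trial {trial.index}: bad plane {plane!r}")
            if onset < t.event_min_onset_ms:
                raise ValueError(f"trial {trial.index}: event before minimum onset")
            if onset + t.event_duration_ms > t.post_cue_ms:
                raise ValueError(f"trial {trial.index}: event overruns post-cue window")
        if k == 2 and onsets[1] - onsets[0] < t.min_onset_to_onset_ms - 1e-9:
            raise ValueError(f"trial {trial.index}: events closer than minimum gap")
    if composition is not None and tuple(counts) != tuple(composition):
        raise ValueError(f"composition {tuple(counts)} != requested {composition}")


def schedule_to_events_frame(schedule: TrialSchedule) -> pd.DataFrame:
    """BIDS-style events table: onset (s), duration (s), trial, block, cue, plane, event_type.

    Onsets are absolute recording times assuming trials are laid out
    back-to-back with the schedule's timing.
    """
    t = schedule.timing
    rows = []
    for trial in schedule.trials:
        t0 = trial.index * t.trial_ms + t.pre_cue_ms   # cue onset, ms
        rows.append({"onset": t0 / 1000.0, "duration": t.post_cue_ms / 1000.0,
                     "trial": trial.index, "block": trial.block, "cue": trial.cue,
                     "plane": "n/a", "event_type": "cue"})
        for onset, plane in trial.events:
            rows.append({"onset": (t0 + onset) / 1000.0,
                         "duration": t.event_duration_ms / 1000.0,
                         "trial": trial.index, "block": trial.block,
                         "cue": trial.cue, "plane": plane,
                         "event_type": "coherent_motion"})
    return pd.DataFrame(rows)


def schedule_from_events_frame(frame: pd.DataFrame,
                               timing: ScheduleTiming | None = None,
                               n_blocks: int = 8) -> TrialSchedule:
    """Rebuild a :class:`TrialSchedule` from its events table."""
    timing = timing or ScheduleTiming()
    trials = []
    for idx, grp in frame.groupby("trial", sort=True):
        cue_rows = grp[grp.event_type == "cue"]
        if len(cue_rows) != 1:
            raise ValueError(f"trial {idx}: expected exactly one cue row")
        cue_row = cue_rows.iloc[0]
        t0 = cue_row.onset * 1000.0
        events = tuple(
            (row.onset * 1000.0 - t0, row.plane)
            for row in grp[grp.event_type == "coherent_motion"].itertuples()
        )
        trials.append(Trial(index=int(idx), block=int(cue_row.block),
                            cue=str(cue_row.cue), events=events))
    return TrialSchedule(trials=trials, timing=timing, n_blocks=n_blocks)
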