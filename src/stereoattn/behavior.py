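"""Response classification, signal-detection summaries, control comparison.

Button presses falling 200-1000 ms after a coherent-motion event in the
attended plane are hits; presses in that window after an ignored-plane event
are false alarms.  Every press receives exactly one label (hit, false alarm
or spurious) and every event exactly one outcome (hit/miss for attended,
false-alarm/correct-rejection for ignored): ambiguous presses go to the
earliest event whose window has not yet consumed a press.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .design import TrialSchedule
from .stats import StatResult, bf10_rank, dprime, wilcoxon_signed_rank

__all__ = ["BehavioralSummary", "classify_responses", "summarize_behavior",
           "control_comparison", "RESPONSE_WINDOW_MS"]

RESPONSE_WINDOW_MS = (200.0, 1000.0)


@dataclass(frozen=True)
class BehavioralSummary:
    """Per-subject behavioral measures (rates as percentages)."""

    n_hits: int
    n_misses: int
    n_fas: int
    n_crs: int
    n_spurious: int
    mean_rt_ms: float          # hits only; NaN if no hits
    dprime: float

    @property
    def hit_rate_pct(self) -> float:
        return 100.0 * self.n_hits / (self.n_hits + self.n_misses)

    @property
    def fa_rate_pct(self) -> float:
        return 100.0 * self.n_fas / (self.n_fas + self.n_crs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hit_rate_pct"] = self.hit_rate_pct
        d["fa_rate_pct"] = self.fa_rate_pct
        return d


def classify_responses(schedule: TrialSchedule, presses: list[float],
                       window_ms: tuple[float, float] = RESPONSE_WINDOW_MS
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign outcomes to events and labels to presses.

    ``presses`` are absolute recording times in ms, time-sorted.  Each press
    is matched to the earliest unconsumed event whose response window
    (inclusive start, exclusive end) contains it.  Returns ``(events,
    presses)`` DataFrames; event outcomes are hit/miss (attended) and
    false_alarm/correct_rejection (ignored); unmatched presses are spurious.
    """
    t = schedule.timing
    events = []
    for rec in schedule.event_records():
        onset_abs = rec["trial"] * t.trial_ms + t.pre_cue_ms + rec["onset_ms"]
        events.append({**rec, "onset_abs_ms": onset_abs, "rt_ms": np.nan,
                       "consumed": False})
    events.sort(key=lambda e: e["onset_abs_ms"])
    if list(presses) != sorted(presses):
        raise ValueError("presses must be time-sorted")

    press_rows = []
    for p in presses:
        label = "spurious"
        for ev in events:
            lo = ev["onset_abs_ms"] + window_ms[0]
            hi = ev["onset_abs_ms"] + window_ms[1]
            if not ev["consumed"] and lo <= p < hi:
                ev["consumed"] = True
                ev["rt_ms"] = p - ev["onset_abs_ms"]
                label = "hit" if ev["attended"] else "false_alarm"
                break
        press_rows.append({"time_ms": p, "label": label})

    for ev in events:
        if ev["attended"]:
            ev["outcome"] = "hit" if ev["consumed"] else "miss"
        else:
            ev["outcome"] = "false_alarm" if ev["consumed"] else "correct_rejection"
        del ev["consumed"]
    return (pd.DataFrame(events),
            pd.DataFrame(press_rows, columns=["time_ms", "label"]))


def summarize_behavior(events: pd.DataFrame, presses: pd.DataFrame,
                       correction: str = "loglinear") -> BehavioralSummary:
    """Counts, rates, mean hit RT and corrected d' from classified outcomes."""
    n_att = int(events["attended"].sum())
    if n_att == 0:
        raise ValueError("no attended events: hit rate undefined")
    counts = events["outcome"].value_counts()
    n_hits = int(counts.get("hit", 0))
    n_misses = int(counts.get("miss", 0))
    n_fas = int(counts.get("false_alarm", 0))
    n_crs = int(counts.get("correct_rejection", 0))
    rts = events.loc[events["outcome"] == "hit", "rt_ms"]
    return BehavioralSummary(
        n_hits=n_hits, n_misses=n_misses, n_fas=n_fas, n_crs=n_crs,
        n_spurious=int((presses["label"] == "spurious").sum()),
        mean_rt_ms=float(rts.mean()) if len(rts) else float("nan"),
        dprime=dprime(n_hits, n_misses, n_fas, n_crs, correction=correction),
    )


def control_comparison(summaries_same_freq: list[BehavioralSummary],
                       summaries_diff_freq: list[BehavioralSummary]
                       ) -> dict[str, StatResult]:
    """Same- vs different-frequency blocks: Wilcoxon + rank Bayes factor.

    Four paired comparisons (mean RT, hit rate, false-alarm rate, d') across
    the same subjects in both block types; used to rule out that observers
    exploit the flicker frequency rather than depth to select the target.
    """
    if len(summaries_same_freq) != len(summaries_diff_freq):
        raise ValueError("need paired subjects across block types")
    measures = {
        "rt_ms": lambda s: s.mean_rt_ms,
        "hit_rate_pct": lambda s: s.hit_rate_pct,
        "fa_rate_pct": lambda s: s.fa_rate_pct,
        "dprime": lambda s: s.dprime,
    }
    out = {}
    for name, get in measures.items():
        x = np.array([get(s) for s in summaries_same_freq])
        y = np.array([get(s) for s in summaries_diff_freq])
        res = wilcoxon_signed_rank(x, y)
        out[name] = StatResult(res.statistic, None, res.p, res.effect_size,
                               bf10=bf10_rank(x, y), method=res.method)
    return out
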