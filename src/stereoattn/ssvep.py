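"""SSVEP amplitude time courses: spectra, Gabor filtering, inference.

Per subject, cue-locked epochs from event-free trials are averaged per
attentional condition (evoked), each channel's spectrum is multiplied by a
Gaussian passband centered on the tagging frequency (a frequency-domain Gabor
filter: frequency FWHM 2 Hz, hence temporal-envelope full width ~441 ms, i.e.
+/-221 ms), and the magnitude of the resulting analytic signal gives the
amplitude envelope.  Envelopes are expressed as percent change against a
pre-cue baseline (-600 to -230 ms), averaged over a posterior electrode
cluster, and collapsed across frequencies/planes into one attended and one
ignored course per subject.  Group inference uses running FDR-corrected
paired t-tests and a mean-amplitude window test (506-948 ms) with a JZS
Bayes factor and within-subject CIs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as spsig

from .montage import SSVEP_CLUSTER
from .preprocess import EpochSet
from .stats import StatResult, morey_ci, paired_t, running_fdr_ttest

__all__ = ["SpectrumResult", "AmplitudeTimeCourse", "amplitude_spectrum",
           "select_cluster", "gabor_timecourse", "gabor_temporal_fwhm_s",
           "baseline_normalize", "collapse_conditions", "subject_ssvep_courses",
           "ssvep_inference", "BASELINE_WINDOW_MS", "TEST_WINDOW_MS"]

BASELINE_WINDOW_MS = (-600.0, -230.0)
TEST_WINDOW_MS = (506.0, 948.0)


@dataclass
class SpectrumResult:
    """Amplitude spectrum per channel (zero-padded FFT of the evoked signal)."""

    freqs: np.ndarray                    # Hz
    amplitude: np.ndarray                # (n_channels, n_freqs)
    window_ms: tuple[float, float]
    ch_names: tuple[str, ...]

    def amplitude_at(self, freq_hz: float) -> np.ndarray:
        """Per-channel amplitude at the bin nearest ``freq_hz``."""
        return self.amplitude[:, int(np.argmin(np.abs(self.freqs - freq_hz)))]


@dataclass
class AmplitudeTimeCourse:
    """Group-level percent-change SSVEP courses with CIs and test masks."""

    times_ms: np.ndarray
    attended_mean: np.ndarray
    ignored_mean: np.ndarray
    ci_half_widths: np.ndarray           # per condition (attended, ignored)
    mask_attended_vs_baseline: np.ndarray
    mask_ignored_vs_baseline: np.ndarray
    mask_between: np.ndarray
    cluster: tuple[str, ...]
    window_ms: tuple[float, float]
    window_means: np.ndarray             # subjects x 2 (attended, ignored)
    window_test: StatResult = None
    window_vs_baseline: dict = field(default_factory=dict)


def amplitude_spectrum(epochs: EpochSet, window_ms: tuple[float, float],
                       pad_to: int = 2 ** 14) -> SpectrumResult:
    """Evoked amplitude spectrum of a window, zero-padded to ``pad_to`` points.

    Epochs are averaged (kept only), the window is linearly detrended per
    channel and the single-sided amplitude ``2 |DFT| / N_window`` is returned;
    the frequency resolution is ``rate / pad_to``.
    """
    t = epochs.times_ms
    sel = (t >= window_ms[0]) & (t < window_ms[1])
    if not sel.any():
        raise ValueError("analysis window lies outside the epochs")
    evoked = epochs.kept().mean(axis=0)[:, sel].astype(float)
    evoked = spsig.detrend(evoked, axis=1)
    n_win = evoked.shape[1]
    if pad_to < n_win:
        raise ValueError("pad_to must be at least the window length")
    amp = 2.0 * np.abs(np.fft.rfft(evoked, n=pad_to, axis=1)) / n_win
    freqs = np.fft.rfftfreq(pad_to, 1.0 / epochs.rate)
    return SpectrumResult(freqs=freqs, amplitude=amp, window_ms=window_ms,
                          ch_names=epochs.montage.labels[:epochs.montage.n_scalp])


def select_cluster(spectrum: SpectrumResult, strategy: str = "fixed",
                   k: int = 22, freqs_hz: tuple[float, ...] = (15.0, 18.0)
                   ) -> tuple[str, ...]:
    """Electrode cluster for the time-course statistics.

    ``fixed`` returns the canonical 22-electrode posterior cluster; ``topk``
    picks the k channels with the highest summed amplitude at the tagging
    frequencies.
    """
    if strategy == "fixed":
        return SSVEP_CLUSTER
    if strategy == "topk":
        score = sum(spectrum.amplitude_at(f) for f in freqs_hz)
        order = np.argsort(score)[::-1][:k]
        return tuple(spectrum.ch_names[i] for i in sorted(order))
    raise ValueError(f"unknown cluster strategy {strategy!r}")


def gabor_temporal_fwhm_s(fwhm_f_hz: float) -> float:
    """Temporal-envelope FWHM dual to a frequency-domain Gaussian FWHM.

    ``FWHM_t = 4 ln 2 / (pi * FWHM_f)`` seconds; 2 Hz maps to ~441 ms
    (half-width +/-221 ms).
    """
    return 4.0 * math.log(2.0) / (math.pi * fwhm_f_hz)


def gabor_timecourse(evoked: np.ndarray, rate: float, f0: float,
                     fwhm_f_hz: float = 2.0) -> np.ndarray:
    """Amplitude envelope at ``f0`` via a frequency-domain Gabor filter.

    The spectrum is multiplied by a Gaussian of FWHM ``fwhm_f_hz`` centered at
    +f0 (negative frequencies zeroed), inverse-transformed, and twice the
    magnitude of the resulting analytic signal is returned — the amplitude a
    stationary sinusoid of amplitude A at f0 would recover as A.
    """
    evoked = np.atleast_2d(np.asarray(evoked, dtype=float))
    if f0 >= rate / 2:
        raise ValueError("center frequency must be below Nyquist")
    sigma_f = fwhm_f_hz / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    if f0 + 3 * sigma_f > rate / 2:
        warnings.warn("Gabor passband extends close to Nyquist", RuntimeWarning)
    n = evoked.shape[1]
    freqs = np.fft.fftfreq(n, 1.0 / rate)
    gauss = np.exp(-0.5 * ((freqs - f0) / sigma_f) ** 2)
    gauss[freqs < 0] = 0.0
    env = 2.0 * np.abs(np.fft.ifft(np.fft.fft(evoked, axis=1) * gauss, axis=1))
    return env


def baseline_normalize(envelope: np.ndarray, times_ms: np.ndarray,
                       baseline_window_ms: tuple[float, float] = BASELINE_WINDOW_MS
                       ) -> np.ndarray:
    """Percent change against the mean of the baseline window, per channel."""
    envelope = np.atleast_2d(envelope)
    sel = (times_ms >= baseline_window_ms[0]) & (times_ms < baseline_window_ms[1])
    if not sel.any():
        raise ValueError("baseline window lies outside the epoch")
    b = envelope[:, sel].mean(axis=1, keepdims=True)
    if np.any(b <= 0):
        raise ValueError("baseline mean must be positive")
    return 100.0 * (envelope - b) / b


def collapse_conditions(courses: dict[tuple[str, float, str], np.ndarray]
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Collapse (cue plane, frequency, plane-of-frequency) cells.

    Cells where the frequency's plane matches the cue are attended, the rest
    ignored; each group is averaged so the subject contributes one attended
    and one ignored course.
    """
    att, ign = [], []
    planes = {cue for cue, _, _ in courses}
    freqs = {f for _, f, _ in courses}
    for cue in planes:
        for f in freqs:
            cells = [(c, ff, p) for (c, ff, p) in courses if c == cue and ff == f]
            if not cells:
                raise ValueError(f"missing condition cell: cue={cue}, freq={f}")
    for (cue, _, plane), course in courses.items():
        (att if plane == cue else ign).append(course)
    if not att or not ign:
        raise ValueError("need both attended and ignored cells")
    return np.mean(att, axis=0), np.mean(ign, axis=0)


def subject_ssvep_courses(epochs: EpochSet,
                          plane_of_freq: tuple[tuple[float, str], ...] = (
                              (15.0, "front"), (18.0, "back")),
                          cluster: tuple[str, ...] = SSVEP_CLUSTER,
                          fwhm_f_hz: float = 2.0,
                          baseline_window_ms: tuple[float, float] = BASELINE_WINDOW_MS
                          ) -> tuple[np.ndarray, np.ndarray]:
    """One subject's attended and ignored percent-change courses.

    ``epochs.labels`` must carry a ``cue`` column (the attended plane).  The
    evoked response per cue condition is detrended, Gabor-filtered at each
    tagging frequency, baseline-normalized per channel, averaged over the
    electrode cluster, and collapsed across the frequency-to-plane mapping.
    """
    if "cue" not in epochs.labels.columns:
        raise ValueError("epochs.labels must contain a 'cue' column")
    t = epochs.times_ms
    idx = epochs.montage.scalp_indices(cluster)
    courses = {}
    for cue in sorted(epochs.labels["cue"].unique()):
        sel = (epochs.labels["cue"] == cue).to_numpy()
        kept = epochs.kept(sel)
        if kept.shape[0] == 0:
            raise ValueError(f"no kept epochs for cue condition {cue!r}")
        evoked = spsig.detrend(kept.mean(axis=0).astype(float), axis=1)
        for f0, plane in plane_of_freq:
            env = gabor_timecourse(evoked[:epochs.montage.n_scalp], epochs.rate,
                                   f0, fwhm_f_hz)
            pct = baseline_normalize(env, t, baseline_window_ms)
            courses[(cue, f0, plane)] = pct[idx].mean(axis=0)
    return collapse_conditions(courses)


def _window_mean(course: np.ndarray, times_ms: np.ndarray,
                 window_ms: tuple[float, float]) -> float:
    sel = (times_ms >= window_ms[0]) & (times_ms < window_ms[1])
    return float(course[sel].mean())


def ssvep_inference(attended: np.ndarray, ignored: np.ndarray,
                    times_ms: np.ndarray,
                    window_ms: tuple[float, float] = TEST_WINDOW_MS,
                    test_range_ms: tuple[float, float] = (0.0, 2000.0),
                    fwhm_f_hz: float = 2.0, q: float = 0.05,
                    cluster: tuple[str, ...] = SSVEP_CLUSTER
                    ) -> AmplitudeTimeCourse:
    """Group inference on subjects x timepoints percent-change courses.

    Running FDR-corrected paired t-tests compare each condition against its
    (zero-mean) baseline and the two conditions against each other over the
    post-cue range, excluding one temporal filter width at the epoch edges.
    Mean amplitudes in the summary window are tested with a paired t-test and
    JZS Bayes factor; Cousineau-Morey CI half-widths accompany the means.
    """
    attended = np.asarray(attended, dtype=float)
    ignored = np.asarray(ignored, dtype=float)
    if attended.shape != ignored.shape or attended.ndim != 2:
        raise ValueError("attended/ignored must be matching subjects x timepoints")
    edge_ms = gabor_temporal_fwhm_s(fwhm_f_hz) * 1000.0
    valid = ((times_ms >= max(test_range_ms[0], times_ms[0] + edge_ms))
             & (times_ms <= min(test_range_ms[1], times_ms[-1] - edge_ms)))
    zeros = np.zeros_like(attended[:, valid])
    m_att, _ = running_fdr_ttest(attended[:, valid], zeros, q=q)
    m_ign, _ = running_fdr_ttest(ignored[:, valid], zeros, q=q)
    m_btw, _ = running_fdr_ttest(attended[:, valid], ignored[:, valid], q=q)
    full = np.zeros((3, times_ms.size), dtype=bool)
    full[0, valid], full[1, valid], full[2, valid] = m_att, m_ign, m_btw

    wm = np.column_stack([
        [_window_mean(c, times_ms, window_ms) for c in attended],
        [_window_mean(c, times_ms, window_ms) for c in ignored],
    ])
    between = paired_t(wm[:, 0], wm[:, 1], with_bf=True)
    vs_baseline = {
        "attended": paired_t(wm[:, 0], np.zeros(wm.shape[0]), with_bf=True),
        "ignored": paired_t(wm[:, 1], np.zeros(wm.shape[0]), with_bf=True),
    }
    return AmplitudeTimeCourse(
        times_ms=times_ms,
        attended_mean=attended.mean(axis=0),
        ignored_mean=ignored.mean(axis=0),
        ci_half_widths=morey_ci(wm),
        mask_attended_vs_baseline=full[0],
        mask_ignored_vs_baseline=full[1],
        mask_between=full[2],
        cluster=tuple(cluster),
        window_ms=window_ms,
        window_means=wm,
        window_test=between,
        window_vs_baseline=vs_baseline,
    )
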