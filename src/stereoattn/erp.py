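"""Event-related potentials: low-pass, event epochs, SN and P3b window tests.

Continuous data are low-passed at 11.5 Hz (zero-phase FIR) so the steady-state
response does not bias the transients, then epoched from -100 to 700 ms around
coherent-motion events with correct behavioral outcomes (hits for attended
events, correct rejections for ignored ones).  After the standard rejection /
reference / CSD chain and baseline correction (-100 to 0 ms), channels are
averaged within a bilateral parieto-occipital cluster (selection negativity,
200-350 ms) and a centro-parietal cluster (P3b, 400-600 ms); the per-subject
window means enter paired frequentist and Bayesian t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as spsig

from .montage import SN_CLUSTER, P3B_CLUSTER
from .preprocess import EpochSet
from .simulate import ContinuousRecording
from .stats import paired_t, morey_ci

__all__ = ["ErpResult", "lowpass_for_erp", "design_erp_lowpass",
           "select_correct_response_events", "baseline_correct", "erp_windows",
           "SN_WINDOW_MS", "P3B_WINDOW_MS", "ERP_EPOCH_MS", "ERP_BASELINE_MS"]

SN_WINDOW_MS = (200.0, 350.0)
P3B_WINDOW_MS = (400.0, 600.0)
ERP_EPOCH_MS = (-100.0, 700.0)
ERP_BASELINE_MS = (-100.0, 0.0)


@dataclass
class ErpResult:
    """Grand averages, per-subject window means and component statistics."""

    times_ms: np.ndarray
    grand_averages: dict            # (component, condition) -> waveform
    window_means: dict              # component -> subjects x 2 (attended, ignored)
    tests: dict                     # component -> StatResult
    ci_half_widths: dict = field(default_factory=dict)
    clusters: dict = field(default_factory=lambda: {"sn": SN_CLUSTER,
                                                    "p3b": P3B_CLUSTER})
    windows_ms: dict = field(default_factory=lambda: {"sn": SN_WINDOW_MS,
                                                      "p3b": P3B_WINDOW_MS})


def design_erp_lowpass(rate: float, cutoff_hz: float = 11.5,
                       stop_hz: float = 15.0) -> np.ndarray:
    """Linear-phase FIR low-pass with its -6 dB point between cutoff and stop.

    A Hamming-windowed sinc sized so the transition band fits between the
    passband edge and ``stop_hz`` (>= 50 dB there, well past the required
    20 dB), leaving < 1 dB ripple below 9 Hz.
    """
    if not (0 < cutoff_hz < rate / 2):
        raise ValueError("cutoff must lie in (0, Nyquist)")
    trans = max(stop_hz - cutoff_hz, 1.0)
    numtaps = int(np.ceil(3.3 * rate / trans)) | 1      # odd for symmetry
    return spsig.firwin(numtaps, (cutoff_hz + stop_hz) / 2.0, fs=rate)


def lowpass_for_erp(recording: ContinuousRecording, cutoff_hz: float = 11.5
                    ) -> ContinuousRecording:
    """Zero-phase low-pass of all channels; returns a filtered copy.

    The symmetric FIR kernel is applied by a single centered convolution,
    which is exactly zero-phase (no peak-latency shift).
    """
    import scipy.fft

    taps = design_erp_lowpass(recording.rate, cutoff_hz)
    out = recording.copy()
    data = out.data.astype(np.float32, copy=False)
    n = data.shape[1]
    k = taps.size
    nfft = scipy.fft.next_fast_len(n + k - 1, real=True)
    spec = scipy.fft.rfft(data, nfft, axis=1)
    spec *= scipy.fft.rfft(taps.astype(np.float32), nfft)
    start = (k - 1) // 2
    out.data = scipy.fft.irfft(spec, nfft, axis=1)[:, start:start + n].astype(
        np.float32)
    return out


def select_correct_response_events(events: pd.DataFrame) -> pd.DataFrame:
    """Keep only events with correct behavioral outcomes.

    Attended events are retained iff they were hits; ignored events iff no
    response fell in their window (correct rejections).  ``events`` is the
    classified table from :func:`stereoattn.behavior.classify_responses`.
    """
    keep = ((events["attended"] & (events["outcome"] == "hit"))
            | (~events["attended"] & (events["outcome"] == "correct_rejection")))
    return events.loc[keep].reset_index(drop=True)


def baseline_correct(epochs: EpochSet,
                     baseline_ms: tuple[float, float] = ERP_BASELINE_MS) -> EpochSet:
    """Subtract the mean of the baseline window per epoch and channel."""
    t = epochs.times_ms
    sel = (t >= baseline_ms[0]) & (t < baseline_ms[1])
    if not sel.any():
        raise ValueError("baseline window lies outside the epoch")
    epochs.data -= epochs.data[:, :, sel].mean(axis=2, keepdims=True).astype(
        epochs.data.dtype)
    return epochs


def _cluster_window_mean(epochs: EpochSet, cluster: tuple[str, ...],
                         window_ms: tuple[float, float],
                         condition_mask: np.ndarray) -> float:
    idx = epochs.montage.scalp_indices(cluster)
    t = epochs.times_ms
    sel = (t >= window_ms[0]) & (t < window_ms[1])
    kept = epochs.kept(condition_mask)
    if kept.shape[0] == 0:
        raise ValueError("no kept epochs in condition")
    return float(kept[:, idx][:, :, sel].mean())


def subject_erp_window_means(epochs: EpochSet) -> dict[str, tuple[float, float]]:
    """One subject's (attended, ignored) window means for SN and P3b.

    ``epochs.labels`` must carry a boolean ``attended`` column; epochs are
    assumed baseline-corrected CSD data.
    """
    if "attended" not in epochs.labels.columns:
        raise ValueError("epochs.labels must contain an 'attended' column")
    att = epochs.labels["attended"].to_numpy(dtype=bool)
    out = {}
    for comp, cluster, window in (("sn", SN_CLUSTER, SN_WINDOW_MS),
                                  ("p3b", P3B_CLUSTER, P3B_WINDOW_MS)):
        out[comp] = (_cluster_window_mean(epochs, cluster, window, att),
                     _cluster_window_mean(epochs, cluster, window, ~att))
    return out


def subject_erp_waveforms(epochs: EpochSet) -> dict[tuple[str, str], np.ndarray]:
    """Cluster-averaged evoked waveforms per component and condition."""
    att = epochs.labels["attended"].to_numpy(dtype=bool)
    out = {}
    for comp, cluster in (("sn", SN_CLUSTER), ("p3b", P3B_CLUSTER)):
        idx = epochs.montage.scalp_indices(cluster)
        for cond, mask in (("attended", att), ("ignored", ~att)):
            kept = epochs.kept(mask)
            out[(comp, cond)] = kept[:, idx].mean(axis=(0, 1))
    return out


def expected_window_contrasts(ground_truth, montage, rate: float = 512.0,
                              cutoff_hz: float = 11.5,
                              head_radius_m: float = 0.085) -> dict[str, float]:
    """Injected attended-vs-ignored contrasts expressed in analysis units.

    Forward-projects each ground-truth component through the linear parts of
    the pipeline — low-pass filter, baseline correction, average reference and
    surface Laplacian — and evaluates the component windows on the cluster
    averages.  Cross-component leakage (filter smearing of one bump into the
    other's window) is included.  This is the value an unbiased analysis
    should recover from a cohort at the population mean gain of 1.
    """
    from .montage import SN_CLUSTER as _SNC, P3B_CLUSTER as _P3C
    from .simulate import _half_cosine_bump, gaussian_topography
    from .splines import csd_transform

    taps = design_erp_lowpass(rate, cutoff_hz)
    t = np.arange(int(round(ERP_EPOCH_MS[0] / 1000 * rate)),
                  int(round(ERP_EPOCH_MS[1] / 1000 * rate))) / rate * 1000.0
    base = (t >= ERP_BASELINE_MS[0]) & (t < ERP_BASELINE_MS[1])
    windows = {"sn": (SN_WINDOW_MS, _SNC), "p3b": (P3B_WINDOW_MS, _P3C)}
    T = csd_transform(montage.positions, head_radius_m=head_radius_m)
    out = {comp: 0.0 for comp in windows}
    for spec in ground_truth.erp_components:
        # temporal course on the epoch axis, filtered and baseline-corrected
        pad = taps.size
        n = t.size + 2 * pad
        course = np.zeros(n)
        width = int(round(spec.width_ms / 1000.0 * rate))
        start = pad + int(round((spec.center_ms - spec.width_ms / 2.0
                                 - ERP_EPOCH_MS[0]) / 1000.0 * rate))
        course[start:start + width] = _half_cosine_bump(width)
        course = np.convolve(course, taps, mode="same")[pad:pad + t.size]
        course -= course[base].mean()
        # spatial factor: topography -> average reference -> CSD -> cluster mean
        w = gaussian_topography(montage, spec.topo_centers, spec.topo_sigma_rad)
        csd = T @ (w - w.mean())
        contrast = spec.amp_attended_uv - spec.amp_ignored_uv
        for comp, (win, cluster) in windows.items():
            sel = (t >= win[0]) & (t < win[1])
            spatial = csd[montage.scalp_indices(cluster)].mean()
            out[comp] += contrast * course[sel].mean() * spatial
    return out


def erp_windows(subject_epochs: list[EpochSet]) -> ErpResult:
    """Group-level ERP analysis across subjects.

    Each entry of ``subject_epochs`` is one subject's baseline-corrected
    event-locked epoch set with ``attended`` labels.  Window means are
    averaged per subject and condition, and each component's attended-vs-
    ignored contrast is tested with a paired t-test plus JZS Bayes factor.
    """
    if len(subject_epochs) < 2:
        raise ValueError("need at least 2 subjects")
    times = subject_epochs[0].times_ms
    means = {comp: [] for comp in ("sn", "p3b")}
    waves: dict[tuple[str, str], list[np.ndarray]] = {}
    for ep in subject_epochs:
        wm = subject_erp_window_means(ep)
        for comp in means:
            means[comp].append(wm[comp])
        for key, w in subject_erp_waveforms(ep).items():
            waves.setdefault(key, []).append(w)
    window_means = {comp: np.array(v) for comp, v in means.items()}
    tests = {comp: paired_t(v[:, 0], v[:, 1], with_bf=True)
             for comp, v in window_means.items()}
    cis = {comp: morey_ci(v) for comp, v in window_means.items()}
    grand = {key: np.mean(v, axis=0) for key, v in waves.items()}
    return ErpResult(times_ms=times, grand_averages=grand,
                     window_means=window_means, tests=tests, ci_half_widths=cis)
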