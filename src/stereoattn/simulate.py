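"""Forward generator for synthetic frequency-tagged EEG with known ground truth.

Every downstream stage (artifact rejection, current-source-density transform,
Gabor amplitude time courses, ERP windows, behavior) is validated against
recordings produced here, because the experiment's real data are not publicly
deposited.  The generator composes, per subject:

* 1/f background noise (64 scalp channels, 512 Hz) plus a non-phase-locked
  occipital alpha rhythm,
* two steady-state responses at the tagging frequencies (15/18 Hz) with an
  occipital topography and condition-dependent amplitude envelopes (phase is
  reset at each trial start, as when the flicker restarts with the trial),
* transient event-related components time-locked to coherent-motion events
  (a posterior negativity at 200-350 ms and a centro-parietal positivity at
  400-600 ms, each a half-cosine bump with its own topography),
* ocular artifacts (blinks on VEOG with a frontal scalp projection, saccadic
  step changes on HEOG) together with a sample-accurate truth table,
* simulated button presses with configurable hit/false-alarm probabilities
  and a shifted log-normal reaction-time distribution.

All randomness flows from a single seed; identical seeds give bit-identical
recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.fft

from .design import TrialSchedule
from .montage import Montage, standard_montage

__all__ = [
    "ContinuousRecording",
    "spatial_mixing_matrix",
    "ErpComponentSpec",
    "GroundTruth",
    "generate_pink_noise",
    "gaussian_topography",
    "inject_ssvep",
    "inject_erp",
    "inject_ocular_artifacts",
    "simulate_presses",
    "generate_subject",
]


@dataclass
class ContinuousRecording:
    """Multichannel time series in microvolts with event markers.

    ``data`` is channels x samples (scalp channels first, in montage order,
    then VEOG and HEOG).  Markers are ``(sample_index, label)`` pairs.
    """

    data: np.ndarray
    rate: float
    montage: Montage
    markers: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[0] != len(self.montage.labels):
            raise ValueError("channel count does not match montage")
        for s, _ in self.markers:
            if not (0 <= s < self.data.shape[1]):
                raise ValueError("marker outside recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def ch_names(self) -> tuple[str, ...]:
        return self.montage.labels

    def marker_samples(self, prefix: str) -> np.ndarray:
        return np.array([s for s, lab in self.markers if lab.startswith(prefix)],
                        dtype=int)

    def copy(self) -> "ContinuousRecording":
        return ContinuousRecording(self.data.copy(), self.rate, self.montage,
                                   list(self.markers))


@dataclass(frozen=True)
class ErpComponentSpec:
    """A transient component: half-cosine bump of given polarity and latency."""

    name: str
    center_ms: float
    width_ms: float
    amp_attended_uv: float
    amp_ignored_uv: float
    topo_centers: tuple[str, ...]
    topo_sigma_rad: float = 0.55


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class GroundTruth:
    """Injectable parameters encoding the experimental findings.

    The default SSVEP envelopes reproduce the study's central result: after
    the attention cue, the tagged response of *both* the attended and the
    ignored plane drops to ~70 % of the pre-cue baseline (a non-selective
    decrease), with no attended-vs-ignored difference.  Set the two levels
    apart to simulate a selective-attention effect instead.
    """

    # SSVEP
    ssvep_amp_uv: float = 5.0
    attended_level: float = 0.70          # post-cue envelope, fraction of baseline
    ignored_level: float = 0.70
    envelope_onset_ms: float = 200.0      # latency of the modulation after the cue
    envelope_ramp_ms: float = 120.0       # sigmoid rise time constant
    plane_of_freq: tuple[tuple[float, str], ...] = ((15.0, "front"), (18.0, "back"))
    ssvep_topo_sigma_rad: float = 0.9
    # ERP components (selection negativity and P3b-like positivity)
    erp_components: tuple[ErpComponentSpec, ...] = (
        ErpComponentSpec("sn", center_ms=275.0, width_ms=200.0,
                         amp_attended_uv=-3.0, amp_ignored_uv=-1.0,
                         topo_centers=("PO7", "PO8")),
        ErpComponentSpec("p3b", center_ms=500.0, width_ms=300.0,
                         amp_attended_uv=3.0, amp_ignored_uv=1.0,
                         topo_centers=("CPz", "Pz")),
    )
    # noise
    noise_exponent: float = 1.0
    noise_rms_uv: float = 10.0
    noise_spatial_sigma_rad: float = 0.5
    noise_independent_frac: float = 0.05
    alpha_amp_uv: float = 3.0
    # artifacts
    blink_rate_per_min: float = 2.0
    saccade_rate_per_min: float = 1.0
    # behavior
    p_hit: float = 0.9265
    p_fa: float = 0.04
    rt_shift_ms: float = 200.0
    rt_median_ms: float = 330.0           # median of the log-normal part
    rt_sigma: float = 0.30
    # inter-subject amplitude variability (log-normal sd of a common gain)
    subject_gain_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.ssvep_amp_uv < 0 or min(self.attended_level, self.ignored_level) < 0:
            raise ValueError("amplitudes and envelope levels must be non-negative")

    def envelope(self, condition: str, times_ms: np.ndarray) -> np.ndarray:
        """Fractional-modulation envelope vs time relative to cue onset.

        Equals 1.0 throughout the pre-cue baseline and transitions smoothly to
        the condition's post-cue level.
        """
        level = {"attended": self.attended_level,
                 "ignored": self.ignored_level}[condition]
        t = np.asarray(times_ms, dtype=float)
        ramp = _sigmoid((t - self.envelope_onset_ms) / self.envelope_ramp_ms * 4.0)
        ramp[t < 0] = 0.0    # envelope is exactly 1.0 before the cue
        return 1.0 + (level - 1.0) * ramp


def generate_pink_noise(n_samples: int, n_channels: int, exponent: float = 1.0,
                        rms_uv: float = 12.0,
                        seed: int | np.random.Generator = 0,
                        mixing: np.ndarray | None = None) -> np.ndarray:
    """1/f^exponent noise with exact per-channel RMS.

    Synthesized in the frequency domain: white Gaussian spectra are shaped by
    ``f**(-exponent/2)`` (power slope ``-exponent``) and inverse-transformed
    (padded to a fast FFT length).  ``mixing``, if given, is a channels x
    channels matrix applied to introduce spatial correlation (rows should be
    unit-norm to preserve variance); per-channel RMS is re-normalized exactly
    either way.
    """
    if not (0.0 <= exponent <= 2.0):
        raise ValueError("exponent must lie in [0, 2]")
    if rms_uv < 0:
        raise ValueError("rms_uv must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if rms_uv == 0 or n_samples == 0:
        return np.zeros((n_channels, n_samples), dtype=np.float32)
    n_fft = scipy.fft.next_fast_len(n_samples, real=True)
    n_freq = n_fft // 2 + 1
    spec = rng.standard_normal((n_channels, 2 * n_freq),
                               dtype=np.float32).view(np.complex64)
    f = np.fft.rfftfreq(n_fft)
    shaping = np.zeros(n_freq, dtype=np.float32)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    spec *= shaping
    x = scipy.fft.irfft(spec, n=n_fft, axis=1)[:, :n_samples]
    if mixing is not None:
        x = (mixing.astype(np.float32) @ x)
    x *= rms_uv / np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return np.ascontiguousarray(x, dtype=np.float32)


def spatial_mixing_matrix(montage: Montage, sigma_rad: float = 0.5,
                          independent_frac: float = 0.2) -> np.ndarray:
    """Unit-row-norm mixing matrix giving scalp noise a volume-conduction-like
    spatial correlation (Gaussian in great-circle distance) plus an
    independent sensor-noise fraction.  EOG rows stay independent.
    """
    n_all = len(montage.labels)
    n_scalp = montage.n_scalp
    pos = montage.positions
    d = np.arccos(np.clip(pos @ pos.T, -1.0, 1.0))
    K = np.exp(-0.5 * (d / sigma_rad) ** 2)
    K /= np.linalg.norm(K, axis=1, keepdims=True)
    M = np.eye(n_all)
    block = (np.sqrt(1.0 - independent_frac) * K
             + np.sqrt(independent_frac) * np.eye(n_scalp))
    block /= np.linalg.norm(block, axis=1, keepdims=True)
    M[:n_scalp, :n_scalp] = block
    return M


def gaussian_topography(montage: Montage, centers: tuple[str, ...],
                        sigma_rad: float = 0.55) -> np.ndarray:
    """Scalp weight map: Gaussian fall-off with great-circle distance.

    Weights are the mean of Gaussians centered on ``centers`` (e.g. between Oz
    and POz for the steady-state response), normalized to a peak of 1.
    """
    pos = montage.positions
    w = np.zeros(montage.n_scalp)
    for c in centers:
        d = np.arccos(np.clip(pos @ montage.position_of(c), -1.0, 1.0))
        w += np.exp(-0.5 * (d / sigma_rad) ** 2)
    return w / w.max()


def inject_ssvep(recording: ContinuousRecording, freq_hz: float,
                 envelope: np.ndarray, topography: np.ndarray,
                 source_amp_uv: float, phase: float = 0.0) -> ContinuousRecording:
    """Add an amplitude-modulated sinusoid at ``freq_hz`` (in place).

    The addition is linear: injecting twice with amplitude A equals injecting
    once with 2A.  ``envelope`` must be sampled on the recording's time axis.
    """
    if freq_hz >= recording.rate / 2:
        raise ValueError("tagging frequency must be below Nyquist")
    if envelope.shape != (recording.n_samples,):
        raise ValueError("envelope must be sampled on the recording time axis")
    t = np.arange(recording.n_samples) / recording.rate
    carrier = np.sin(2 * np.pi * freq_hz * t + phase) * envelope * source_amp_uv
    n_scalp = recording.montage.n_scalp
    recording.data[:n_scalp] += (topography[:, None] * carrier).astype(
        recording.data.dtype)
    return recording


def _half_cosine_bump(n: int) -> np.ndarray:
    """Unit-peak smooth unimodal bump of length n (raised-cosine window)."""
    return 0.5 * (1.0 - np.cos(2 * np.pi * np.arange(n) / max(n - 1, 1)))


def inject_erp(recording: ContinuousRecording, event_samples: np.ndarray,
               spec: ErpComponentSpec, amplitudes_uv: np.ndarray) -> ContinuousRecording:
    """Add a transient component after each event (in place).

    ``amplitudes_uv`` gives the peak amplitude per event (sign included), so
    attended and ignored events can differ.  The waveform is a half-cosine
    bump of ``width_ms`` centered ``center_ms`` after the event onset, scaled
    per channel by a Gaussian topography.
    """
    rate = recording.rate
    width = int(round(spec.width_ms / 1000.0 * rate))
    bump = _half_cosine_bump(width)
    start_off = int(round((spec.center_ms - spec.width_ms / 2.0) / 1000.0 * rate))
    topo = gaussian_topography(recording.montage, spec.topo_centers,
                               spec.topo_sigma_rad)
    n_scalp = recording.montage.n_scalp
    for s, amp in zip(np.asarray(event_samples, dtype=int), amplitudes_uv):
        a = s + start_off
        b = a + width
        if a < 0 or b > recording.n_samples:
            continue
        recording.data[:n_scalp, a:b] += (amp * topo[:, None] * bump).astype(
            recording.data.dtype)
    return recording


def inject_ocular_artifacts(recording: ContinuousRecording,
                            blink_rate_per_min: float = 2.0,
                            saccade_rate_per_min: float = 1.0,
                            seed: int | np.random.Generator = 0
                            ) -> pd.DataFrame:
    """Add blinks and saccades (in place); returns the artifact truth table.

    Blinks are 100-200 ms raised-cosine deflections of 200-400 uV on VEOG with
    a frontal scalp projection; saccades are step changes of 40-80 uV on HEOG
    (above the 30 uV detection criterion) with a small lateral-frontal
    projection.  The truth table lists kind, onset/offset sample and peak
    amplitude of every injected artifact.
    """
    if blink_rate_per_min < 0 or saccade_rate_per_min < 0:
        raise ValueError("artifact rates must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rate = recording.rate
    n = recording.n_samples
    dur_s = n / rate
    mont = recording.montage
    n_scalp = mont.n_scalp
    iveog = mont.index("VEOG")
    iheog = mont.index("HEOG")
    rows: list[dict] = []

    n_blinks = rng.poisson(blink_rate_per_min * dur_s / 60.0)
    frontal = gaussian_topography(mont, ("Fpz",), 0.5) * 0.5
    for _ in range(n_blinks):
        width = int(rng.uniform(0.100, 0.200) * rate)
        amp = rng.uniform(200.0, 400.0)
        a = int(rng.uniform(0, n - width))
        bump = _half_cosine_bump(width)
        recording.data[iveog, a:a + width] += (amp * bump).astype(recording.data.dtype)
        recording.data[:n_scalp, a:a + width] += (amp * frontal[:, None] * bump
                                                  ).astype(recording.data.dtype)
        rows.append({"kind": "blink", "start": a, "stop": a + width, "amp_uv": amp})

    n_sacc = rng.poisson(saccade_rate_per_min * dur_s / 60.0)
    lateral = (gaussian_topography(mont, ("F8",), 0.5)
               - gaussian_topography(mont, ("F7",), 0.5)) * 0.15
    ramp_n = int(0.020 * rate)
    for _ in range(n_sacc):
        hold = int(rng.uniform(0.300, 0.800) * rate)
        amp = rng.uniform(40.0, 80.0) * rng.choice([-1.0, 1.0])
        a = int(rng.uniform(0, n - hold - 2 * ramp_n))
        step = np.concatenate([np.linspace(0, 1, ramp_n), np.ones(hold),
                               np.linspace(1, 0, ramp_n)])
        recording.data[iheog, a:a + step.size] += (amp * step).astype(
            recording.data.dtype)
        recording.data[:n_scalp, a:a + step.size] += (amp * lateral[:, None] * step
                                                      ).astype(recording.data.dtype)
        rows.append({"kind": "saccade", "start": a, "stop": a + step.size,
                     "amp_uv": amp})
    table = pd.DataFrame(rows, columns=["kind", "start", "stop", "amp_uv"])
    return table.sort_values("start", ignore_index=True) if len(table) else table


def simulate_presses(schedule: TrialSchedule, p_hit: float, p_fa: float,
                     rt_shift_ms: float = 200.0, rt_median_ms: float = 330.0,
                     rt_sigma: float = 0.30,
                     seed: int | np.random.Generator = 0) -> list[float]:
    """Simulated button-press times (ms, absolute recording time).

    Each attended event elicits a press with probability ``p_hit``; each
    ignored event with probability ``p_fa``.  Reaction times follow a shifted
    log-normal constrained to the 200-1000 ms response window.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = schedule.timing
    presses = []
    for rec in schedule.event_records():
        p = p_hit if rec["attended"] else p_fa
        if rng.uniform() >= p:
            continue
        rt = rt_shift_ms + rt_median_ms * np.exp(rng.normal(0.0, rt_sigma))
        rt = float(np.clip(rt, 201.0, 995.0))
        t_cue = rec["trial"] * t.trial_ms + t.pre_cue_ms
        presses.append(t_cue + rec["onset_ms"] + rt)
    return sorted(presses)


def generate_subject(schedule: TrialSchedule, ground_truth: GroundTruth,
                     montage: Montage | None = None, rate: float = 512.0,
                     seed: int | np.random.Generator = 0
                     ) -> tuple[ContinuousRecording, pd.DataFrame, list[float]]:
    """One subject's continuous recording, artifact truth table and presses.

    Trials are laid out back-to-back with the schedule's timing.  Markers:
    ``cue:<plane>`` at each cue onset, ``event:<plane>:<att|ign>`` at each
    coherent-motion onset, ``press`` at each button press.  Deterministic for
    a fixed seed.
    """
    montage = montage or standard_montage()
    root = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ss = np.random.SeedSequence(int(root.integers(2**31)))
    s_noise, s_alpha, s_art, s_beh, s_subj = ss.spawn(5)

    gt = ground_truth
    timing = schedule.timing
    trial_n = int(round(timing.trial_ms / 1000.0 * rate))
    n_samples = trial_n * len(schedule)
    n_ch = len(montage.labels)

    # per-subject gain (inter-individual amplitude variability)
    gain = float(np.exp(np.random.default_rng(s_subj).normal(0.0, gt.subject_gain_sd)))

    mixing = spatial_mixing_matrix(montage, gt.noise_spatial_sigma_rad,
                                   gt.noise_independent_frac)
    data = generate_pink_noise(n_samples, n_ch, gt.noise_exponent,
                               gt.noise_rms_uv, np.random.default_rng(s_noise),
                               mixing=mixing)
    rec = ContinuousRecording(data=data, rate=rate, montage=montage)

    # --- non-phase-locked occipital alpha, random phase/amplitude per trial
    if gt.alpha_amp_uv > 0:
        arng = np.random.default_rng(s_alpha)
        occ = gaussian_topography(montage, ("POz", "Oz"), 0.7)
        t_trial = np.arange(trial_n) / rate
        for i in range(len(schedule)):
            amp = gt.alpha_amp_uv * arng.rayleigh(1.0) / np.sqrt(np.pi / 2)
            ph = arng.uniform(0, 2 * np.pi)
            burst = amp * np.sin(2 * np.pi * 10.0 * t_trial + ph)
            sl = slice(i * trial_n, (i + 1) * trial_n)
            rec.data[:montage.n_scalp, sl] += (occ[:, None] * burst).astype(
                rec.data.dtype)

    # --- steady-state responses: phase reset at each trial start
    topo = gaussian_topography(montage, ("Oz", "POz"), gt.ssvep_topo_sigma_rad)
    t_trial_ms = (np.arange(trial_n) / rate) * 1000.0 - timing.pre_cue_ms
    t_trial_s = np.arange(trial_n) / rate
    cue_samples = []
    for freq, plane in gt.plane_of_freq:
        carrier = np.sin(2 * np.pi * freq * t_trial_s)
        env_att = gt.envelope("attended", t_trial_ms)
        env_ign = gt.envelope("ignored", t_trial_ms)
        for i, trial in enumerate(schedule.trials):
            env = env_att if trial.cue == plane else env_ign
            sl = slice(i * trial_n, (i + 1) * trial_n)
            rec.data[:montage.n_scalp, sl] += (
                gain * gt.ssvep_amp_uv * topo[:, None] * (carrier * env)
            ).astype(rec.data.dtype)

    # --- markers and transient components
    markers: list[tuple[int, str]] = []
    ev_samples: list[int] = []
    ev_attended: list[bool] = []
    for i, trial in enumerate(schedule.trials):
        cue_s = i * trial_n + int(round(timing.pre_cue_ms / 1000.0 * rate))
        cue_samples.append(cue_s)
        markers.append((cue_s, f"cue:{trial.cue}"))
        for onset, plane in trial.events:
            s = cue_s + int(round(onset / 1000.0 * rate))
            att = plane == trial.cue
            markers.append((s, f"event:{plane}:{'att' if att else 'ign'}"))
            ev_samples.append(s)
            ev_attended.append(att)
    ev_samples_arr = np.array(ev_samples, dtype=int)
    for spec in gt.erp_components:
        amps = np.where(ev_attended, spec.amp_attended_uv, spec.amp_ignored_uv) * gain
        inject_erp(rec, ev_samples_arr, spec, amps)

    # --- artifacts and behavior
    truth = inject_ocular_artifacts(rec, gt.blink_rate_per_min,
                                    gt.saccade_rate_per_min,
                                    np.random.default_rng(s_art))
    presses = simulate_presses(schedule, gt.p_hit, gt.p_fa, gt.rt_shift_ms,
                               gt.rt_median_ms, gt.rt_sigma,
                               np.random.default_rng(s_beh))
    for p_ms in presses:
        s = int(round(p_ms / 1000.0 * rate))
        if s < n_samples:
            markers.append((s, "press"))
    rec.markers = sorted(markers)
    return rec, truth, presses
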