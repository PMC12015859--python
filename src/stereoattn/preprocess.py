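"""Epoching and the artifact / reference chain.

The processing order is fixed: DC removal on the continuous data, epoch
extraction, blink rejection (adaptive VEOG threshold), saccade rejection
(HEOG step criterion), statistical channel-contamination scan with spherical
spline interpolation of salvageable channels (epochs with more than ``cap``
contaminated channels are discarded), average reference, and finally the
surface Laplacian to current source density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import Montage
from .simulate import ContinuousRecording
from .splines import csd_transform, interpolation_operator

__all__ = ["EpochSet", "PreprocParams", "remove_dc", "extract_epochs",
           "detect_blinks", "detect_saccades", "scan_channel_contamination",
           "spherical_spline_interpolate", "rereference_average",
           "surface_laplacian", "preprocess_epochs"]

logger = logging.getLogger(__name__)

KEPT = "kept"
REJ_BLINK = "rejected_blink"
REJ_SACC = "rejected_saccade"
REJ_CHAN = "rejected_channels"


@dataclass
class EpochSet:
    """Epochs x channels x samples with rejection bookkeeping.

    The anchor sample maps to t = 0 ms; windows are inclusive-start,
    exclusive-end, so a (-1000, 2000) ms window at 512 Hz holds 1536 samples.
    Rejected epochs stay in ``data`` but are excluded from every average via
    ``kept_mask``.
    """

    data: np.ndarray                      # (n_epochs, n_channels, n_samples)
    window_ms: tuple[float, float]
    rate: float
    montage: Montage
    anchor: str = "cue"
    status: np.ndarray = None             # per-epoch string status
    interpolated: list[set] = None        # per-epoch set of channel indices
    labels: pd.DataFrame = None           # per-epoch metadata (condition, ...)
    n_dropped_edge: int = 0
    is_csd: bool = False

    def __post_init__(self) -> None:
        if self.window_ms[0] >= self.window_ms[1]:
            raise ValueError("window start must precede end")
        n = self.data.shape[0]
        if self.status is None:
            self.status = np.full(n, KEPT, dtype=object)
        if self.interpolated is None:
            self.interpolated = [set() for _ in range(n)]
        if self.labels is None:
            self.labels = pd.DataFrame(index=range(n))

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.window_ms[0] + np.arange(n) / self.rate * 1000.0

    @property
    def kept_mask(self) -> np.ndarray:
        return self.status == KEPT

    def kept(self, mask: np.ndarray | None = None) -> np.ndarray:
        sel = self.kept_mask if mask is None else (self.kept_mask & mask)
        return self.data[sel]

    def channel_index(self, label: str) -> int:
        return self.montage.index(label)

    def scalp_slice(self) -> slice:
        return slice(0, self.montage.n_scalp)

    def rejection_summary(self) -> pd.DataFrame:
        vals, counts = np.unique(self.status, return_counts=True)
        return pd.DataFrame({"status": vals, "n_epochs": counts})


@dataclass(frozen=True)
class PreprocParams:
    """Tunable preprocessing parameters (defaults follow common practice)."""

    blink_floor_uv: float = 60.0
    blink_k_mad: float = 5.0
    saccade_step_uv: float = 30.0
    contamination_cap: int = 12
    spline_m: int = 4
    spline_lambda: float = 1e-5
    spline_terms: int = 50
    head_radius_m: float = 0.085
    apply_csd: bool = True


def remove_dc(recording: ContinuousRecording) -> ContinuousRecording:
    """Subtract each channel's mean over the full recording (in place)."""
    recording.data -= recording.data.mean(axis=1, keepdims=True).astype(
        recording.data.dtype)
    return recording


def extract_epochs(recording: ContinuousRecording, anchors: np.ndarray,
                   window_ms: tuple[float, float], anchor_type: str = "cue",
                   labels: pd.DataFrame | None = None) -> EpochSet:
    """Cut fixed windows around anchor samples.

    Anchors whose window would run past either edge of the recording are
    dropped (the count is logged and recorded on the returned set).
    """
    rate = recording.rate
    start = int(round(window_ms[0] / 1000.0 * rate))
    n_samp = int(round((window_ms[1] - window_ms[0]) / 1000.0 * rate))
    anchors = np.asarray(anchors, dtype=int)
    ok = (anchors + start >= 0) & (anchors + start + n_samp <= recording.n_samples)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("extract_epochs: dropped %d anchors at recording edges", n_dropped)
    idx = anchors[ok]
    data = np.stack([recording.data[:, a + start:a + start + n_samp] for a in idx]) \
        if len(idx) else np.zeros((0, recording.data.shape[0], n_samp),
                                  dtype=recording.data.dtype)
    if labels is not None:
        labels = labels.loc[ok].reset_index(drop=True)
    return EpochSet(data=data, window_ms=window_ms, rate=rate,
                    montage=recording.montage, anchor=anchor_type,
                    labels=labels, n_dropped_edge=n_dropped)


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def detect_blinks(epochs: EpochSet, veog_channel: str = "VEOG",
                  floor_uv: float = 60.0, k: float = 5.0) -> np.ndarray:
    """Adaptive-threshold blink flags from VEOG peak-to-peak amplitudes.

    The threshold is ``max(floor_uv, median + k * MAD)`` of the per-epoch
    peak-to-peak distribution, re-estimated once after removing the epochs
    flagged in the first pass; it never drops below ``floor_uv``.
    """
    if veog_channel not in epochs.montage.labels:
        raise ValueError(f"channel {veog_channel!r} not in montage")
    ch = epochs.channel_index(veog_channel)
    ptp = np.ptp(epochs.data[:, ch, :].astype(float), axis=1)
    if ptp.size == 0:
        return np.zeros(0, dtype=bool)
    thr = max(floor_uv, np.median(ptp) + k * _mad(ptp))
    clean = ptp[ptp <= thr]
    if clean.size:
        thr = max(floor_uv, np.median(clean) + k * _mad(clean))
    return ptp > thr


def detect_saccades(epochs: EpochSet, heog_channel: str = "HEOG",
                    step_uv: float = 30.0, window_ms: float = 100.0) -> np.ndarray:
    """Flag epochs whose HEOG steps between consecutive 100-ms window means.

    The two windows slide sample-by-sample so a step is measured at full
    height wherever it occurs in the epoch.
    """
    if heog_channel not in epochs.montage.labels:
        raise ValueError(f"channel {heog_channel!r} not in montage")
    ch = epochs.channel_index(heog_channel)
    w = int(round(window_ms / 1000.0 * epochs.rate))
    x = epochs.data[:, ch, :].astype(float)
    if x.shape[1] < 2 * w:
        return np.zeros(epochs.n_epochs, dtype=bool)
    c = np.cumsum(np.pad(x, ((0, 0), (1, 0))), axis=1)
    means = (c[:, w:] - c[:, :-w]) / w               # sliding window means
    diffs = np.abs(means[:, w:] - means[:, :-w])     # consecutive windows
    return diffs.max(axis=1) > step_uv


def scan_channel_contamination(epochs: EpochSet, cap: int = 12
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Statistical artifact scan over kept epochs and scalp channels.

    Per epoch x channel, three statistics are computed: absolute maximum,
    standard deviation and maximum absolute first difference.  A channel is
    contaminated in an epoch when any statistic exceeds its pooled
    (epoch x channel) ``median + 3 * IQR`` limit.  Epochs with more than
    ``cap`` contaminated channels are marked rejected; the remaining flags
    denote channels to interpolate.  Returns ``(flags, rejected)`` where
    ``flags`` is (n_epochs, n_scalp) boolean.
    """
    kept_idx = np.flatnonzero(epochs.kept_mask)
    if kept_idx.size < 8:
        raise ValueError("need at least 8 kept epochs for stable statistics")
    sl = epochs.scalp_slice()
    x = epochs.data[kept_idx, sl, :]
    stats = np.stack([
        np.abs(x).max(axis=2),
        x.std(axis=2, dtype=np.float64).astype(x.dtype),
        np.abs(np.diff(x, axis=2)).max(axis=2),
    ])                                               # (3, n_kept, n_scalp)
    flags_kept = np.zeros(stats.shape[1:], dtype=bool)
    for s in stats:
        q1, med, q3 = np.percentile(s, [25, 50, 75])
        flags_kept |= s > med + 3.0 * (q3 - q1)
    flags = np.zeros((epochs.n_epochs, epochs.montage.n_scalp), dtype=bool)
    flags[kept_idx] = flags_kept
    n_bad = flags.sum(axis=1)
    rejected = epochs.kept_mask & (n_bad > cap)
    epochs.status[rejected] = REJ_CHAN
    for i in kept_idx:
        if not rejected[i]:
            epochs.interpolated[i] |= set(np.flatnonzero(flags[i]))
    return flags, rejected


def spherical_spline_interpolate(epochs: EpochSet, montage: Montage | None = None,
                                 bad_channel_sets: list[set] | None = None,
                                 m: int = 4, lam: float = 1e-5,
                                 n_terms: int = 50) -> EpochSet:
    """Replace contaminated channels by their spherical-spline estimate.

    Operates in place on kept epochs; good channels are untouched.  Operators
    are cached per distinct bad-channel set.
    """
    montage = montage or epochs.montage
    bad_sets = bad_channel_sets if bad_channel_sets is not None else epochs.interpolated
    pos = montage.positions
    all_idx = np.arange(montage.n_scalp)
    cache: dict[frozenset, np.ndarray] = {}
    for i in np.flatnonzero(epochs.kept_mask):
        bad = frozenset(bad_sets[i])
        if not bad:
            continue
        if bad not in cache:
            bad_arr = np.array(sorted(bad))
            good_arr = np.setdiff1d(all_idx, bad_arr)
            cache[bad] = interpolation_operator(pos, good_arr, bad_arr,
                                                m=m, lam=lam, n_terms=n_terms)
        bad_arr = np.array(sorted(bad))
        good_arr = np.setdiff1d(all_idx, bad_arr)
        epochs.data[i, bad_arr, :] = (cache[bad] @ epochs.data[i, good_arr, :]
                                      ).astype(epochs.data.dtype)
    return epochs


def rereference_average(epochs: EpochSet) -> EpochSet:
    """Average reference over scalp channels (EOG untouched), in place."""
    sl = epochs.scalp_slice()
    mean = epochs.data[:, sl, :].mean(axis=1, keepdims=True)
    epochs.data[:, sl, :] -= mean.astype(epochs.data.dtype)
    return epochs


def surface_laplacian(epochs: EpochSet, montage: Montage | None = None,
                      m: int = 4, lam: float = 1e-5, n_terms: int = 50,
                      head_radius_m: float = 0.085) -> EpochSet:
    """Transform scalp channels to current source density (uV/m^2), in place.

    The operator is linear, so it commutes with epoch averaging.  EOG
    channels are zeroed (they have no scalp position).
    """
    montage = montage or epochs.montage
    T = csd_transform(montage.positions, m=m, lam=lam, n_terms=n_terms,
                      head_radius_m=head_radius_m).astype(epochs.data.dtype)
    sl = epochs.scalp_slice()
    epochs.data[:, sl, :] = np.matmul(T[None, :, :], epochs.data[:, sl, :])
    epochs.data[:, montage.n_scalp:, :] = 0.0
    epochs.is_csd = True
    return epochs


def preprocess_epochs(recording: ContinuousRecording, anchors: np.ndarray,
                      window_ms: tuple[float, float], anchor_type: str = "cue",
                      labels: pd.DataFrame | None = None,
                      params: PreprocParams | None = None) -> EpochSet:
    """The full chain in the canonical order.

    Blink and saccade rejection run first, then the contamination scan with
    spline interpolation, then average reference and (optionally) the surface
    Laplacian.
    """
    p = params or PreprocParams()
    epochs = extract_epochs(recording, anchors, window_ms, anchor_type, labels)
    blink = detect_blinks(epochs, floor_uv=p.blink_floor_uv, k=p.blink_k_mad)
    epochs.status[blink & epochs.kept_mask] = REJ_BLINK
    sacc = detect_saccades(epochs, step_uv=p.saccade_step_uv)
    epochs.status[sacc & epochs.kept_mask] = REJ_SACC
    scan_channel_contamination(epochs, cap=p.contamination_cap)
    spherical_spline_interpolate(epochs, m=p.spline_m, lam=p.spline_lambda,
                                 n_terms=p.spline_terms)
    rereference_average(epochs)
    if p.apply_csd:
        surface_laplacian(epochs, m=p.spline_m, lam=p.spline_lambda,
                          n_terms=p.spline_terms, head_radius_m=p.head_radius_m)
    return epochs
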