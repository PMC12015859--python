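"""64-channel 10-10 scalp montage with bipolar EOG channels.

Positions are taken from MNE's idealized 10-05 montage and projected onto the
unit sphere; only labels and spherical geometry are used downstream (spline
interpolation, surface Laplacian, topography weights).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["Montage", "standard_montage", "SSVEP_CLUSTER", "SN_CLUSTER", "P3B_CLUSTER"]

# Electrode clusters used for the statistical analyses: a large posterior
# cluster for the SSVEP time courses, a bilateral parieto-occipital cluster
# for the selection negativity and a centro-parietal cluster for the P3b.
SSVEP_CLUSTER = ("P9", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
                 "P10", "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2",
                 "I1", "Iz", "I2")
SN_CLUSTER = ("TP7", "P9", "P7", "P5", "PO7", "TP8", "P6", "P8", "P10", "PO8")
P3B_CLUSTER = ("Cz", "CP1", "CPz", "CP2", "Pz")

_SCALP_64 = (
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P9", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P10",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "I1", "Iz", "I2",
)
# sanity: 64 scalp sites, superset of all analysis clusters
assert len(_SCALP_64) == 65 - 1


@dataclass(frozen=True)
class Montage:
    """Channel labels plus unit-sphere positions for the scalp channels.

    ``labels`` lists scalp channels followed by the bipolar EOG derivations;
    ``positions`` has one unit-norm 3D row per scalp channel.
    """

    labels: tuple[str, ...]
    positions: np.ndarray          # (n_scalp, 3), unit norm
    eog_labels: tuple[str, ...] = ("VEOG", "HEOG")

    def __post_init__(self) -> None:
        scalp = self.scalp_labels
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate channel labels")
        if self.positions.shape != (len(scalp), 3):
            raise ValueError("positions must be (n_scalp, 3)")
        if not np.allclose(np.linalg.norm(self.positions, axis=1), 1.0, atol=1e-6):
            raise ValueError("positions must be unit-norm")
        for cluster in (SSVEP_CLUSTER, SN_CLUSTER, P3B_CLUSTER):
            missing = set(cluster) - set(scalp)
            if missing:
                raise ValueError(f"montage missing cluster electrodes: {sorted(missing)}")

    @property
    def scalp_labels(self) -> tuple[str, ...]:
        return tuple(l for l in self.labels if l not in self.eog_labels)

    @property
    def n_scalp(self) -> int:
        return len(self.scalp_labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def scalp_indices(self, labels: tuple[str, ...] | list[str]) -> np.ndarray:
        """Row indices of ``labels`` within the scalp-channel block."""
        scalp = self.scalp_labels
        return np.array([scalp.index(l) for l in labels])

    def position_of(self, label: str) -> np.ndarray:
        return self.positions[self.scalp_labels.index(label)]


def standard_montage() -> Montage:
    """64 scalp channels (10-10 nomenclature, unit sphere) plus VEOG/HEOG."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = mne.channels.make_standard_montage("standard_1005")
    ch_pos = std.get_positions()["ch_pos"]
    pos = np.array([ch_pos[name] for name in _SCALP_64], dtype=float)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)   # project onto unit sphere
    return Montage(labels=_SCALP_64 + ("VEOG", "HEOG"), positions=pos)
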