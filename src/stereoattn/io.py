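"""File interchange: EDF+ recordings, events TSV, epoch directories, JSON.

Recordings are written as EDF+C (16-bit, physical dimension uV, 1-second data
records) with markers stored as EDF+ annotations; reading goes through MNE's
EDF reader, which acts as an independent check on the writer.  Event tables
are BIDS-style TSV; epoch sets are a directory of one binary array plus JSON
metadata; results are plain JSON with SHA-256 checksums.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import Montage, standard_montage
from .preprocess import EpochSet
from .simulate import ContinuousRecording

__all__ = ["write_edf", "read_edf", "write_events_tsv", "read_events_tsv",
           "write_epochs", "read_epochs", "write_json", "sha256_of"]


def _pad(text: str, n: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > n:
        raise ValueError(f"EDF header field too long: {text!r} > {n}")
    return b.ljust(n)


def write_edf(path: str | Path, recording: ContinuousRecording) -> Path:
    """Write a recording as EDF+C with markers as annotations.

    Each channel is scaled to its own symmetric physical range, so the
    quantization step is ``2 * max|x| / 65535`` uV.  The last data record is
    zero-padded to a full second.
    """
    path = Path(path)
    rate = recording.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(rate))                      # samples per 1 s record
    data = np.asarray(recording.data, dtype=float)
    n_ch, n_samp = data.shape
    n_rec = int(np.ceil(n_samp / spr))

    # annotation TALs per record
    tals: list[bytes] = []
    markers_by_rec: dict[int, list[tuple[float, str]]] = {}
    for s, lab in recording.markers:
        markers_by_rec.setdefault(s // spr, []).append((s / rate, lab))
    for r in range(n_rec):
        chunk = f"+{r}\x14\x14\x00".encode("ascii")
        for onset, lab in markers_by_rec.get(r, []):
            chunk += f"+{onset:.6f}\x14{lab}\x14\x00".encode("utf-8")
        tals.append(chunk)
    ann_bytes = max(len(t) for t in tals) + 2
    ann_spr = (ann_bytes + 1) // 2              # 2 bytes per 16-bit sample

    pmax = np.maximum(np.ceil(np.abs(data).max(axis=1)), 1.0)
    ns = n_ch + 1
    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate X X X X", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (ns + 1)), 8),
        _pad("EDF+C", 44),
        _pad(str(n_rec), 8),
        _pad("1", 8),
        _pad(str(ns), 4),
    ])
    labels = [l for l in recording.ch_names] + ["EDF Annotations"]
    fields = [
        [_pad(l, 16) for l in labels],
        [_pad("", 80)] * ns,
        [_pad("uV", 8)] * n_ch + [_pad("", 8)],
        [_pad(str(int(-p)), 8) for p in pmax] + [_pad("-1", 8)],
        [_pad(str(int(p)), 8) for p in pmax] + [_pad("1", 8)],
        [_pad("-32768", 8)] * ns,
        [_pad("32767", 8)] * ns,
        [_pad("", 80)] * ns,
        [_pad(str(spr), 8)] * n_ch + [_pad(str(ann_spr), 8)],
        [_pad("", 32)] * ns,
    ]
    header += b"".join(b"".join(f) for f in fields)

    scale = pmax / 32767.0
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            seg = np.zeros((n_ch, spr))
            block = data[:, r * spr:(r + 1) * spr]
            seg[:, :block.shape[1]] = block
            dig = np.round(seg / scale[:, None]).astype("<i2")
            fh.write(dig.tobytes())
            ann = tals[r].ljust(ann_spr * 2, b"\x00")
            fh.write(ann)
    return path


def read_edf(path: str | Path, montage: Montage | None = None
             ) -> ContinuousRecording:
    """Read an EDF+ file back into a recording (via MNE's EDF reader)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    montage = montage or standard_montage()
    if tuple(raw.ch_names) != tuple(montage.labels):
        raise ValueError("EDF channel labels do not match the montage")
    data = (raw.get_data() * 1e6).astype(np.float32)      # V -> uV
    rate = float(raw.info["sfreq"])
    markers = [(int(round(ann["onset"] * rate)), str(ann["description"]))
               for ann in raw.annotations]
    markers = [m for m in markers if m[1] not in ("", "EDF Annotations")]
    return ContinuousRecording(data=data, rate=rate, montage=montage,
                               markers=sorted(markers))


def write_events_tsv(path: str | Path, events: pd.DataFrame) -> Path:
    path = Path(path)
    events.to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    # keep literal "n/a" strings (BIDS convention) instead of NaN
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])


def write_epochs(directory: str | Path, epochs: EpochSet) -> Path:
    """Serialize an epoch set: data.npy plus metadata.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "data.npy", epochs.data)
    meta = {
        "window_ms": list(epochs.window_ms),
        "rate": epochs.rate,
        "anchor": epochs.anchor,
        "status": [str(s) for s in epochs.status],
        "interpolated": [sorted(int(i) for i in s) for s in epochs.interpolated],
        "labels": epochs.labels.to_dict(orient="list"),
        "n_dropped_edge": epochs.n_dropped_edge,
        "is_csd": epochs.is_csd,
        "channels": list(epochs.montage.labels),
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=1))
    return directory


def read_epochs(directory: str | Path, montage: Montage | None = None) -> EpochSet:
    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text())
    montage = montage or standard_montage()
    if meta["channels"] != list(montage.labels):
        raise ValueError("epoch directory channels do not match the montage")
    ep = EpochSet(
        data=np.load(directory / "data.npy"),
        window_ms=tuple(meta["window_ms"]),
        rate=meta["rate"],
        montage=montage,
        anchor=meta["anchor"],
        status=np.array(meta["status"], dtype=object),
        interpolated=[set(s) for s in meta["interpolated"]],
        labels=pd.DataFrame(meta["labels"]),
        n_dropped_edge=meta["n_dropped_edge"],
        is_csd=meta["is_csd"],
    )
    return ep


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(payload, indent=1, default=default))
    return path
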