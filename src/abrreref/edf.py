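"""EDF+ export and import of continuous recordings.

Writing: a small EDF+C writer (16-bit samples, physical units uV, stimulus
onsets in an ``EDF Annotations`` signal as standard time-stamped annotation
lists).  Reading goes through :func:`mne.io.read_raw_edf`, so files written
by any compliant recorder — not just this package — can enter the pipeline.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .simulate import ContinuousRecording

__all__ = ["write_edf", "read_edf", "EVENT_LABEL"]

#: Annotation text used for stimulus onsets.
EVENT_LABEL = "click"

_CANDIDATE_RECORD_S = (0.01, 0.02, 0.025, 0.05, 0.1, 0.2, 0.5, 1.0)


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds {width} ascii characters")
    return s.ljust(width).encode("ascii")


def _num8(value: float) -> str:
    """Shortest decimal representation of ``value`` fitting 8 characters."""
    for prec in (6, 5, 4, 3, 2, 1):
        s = f"{value:.{prec}g}"
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot format {value} in 8 characters")


def _pick_record_duration(fs: float, n_channels: int) -> float:
    """Longest candidate duration with integer samples/record and a record
    size comfortably below the 61440-byte EDF recommendation."""
    best = None
    for d in _CANDIDATE_RECORD_S:
        spr = fs * d
        if abs(spr - round(spr)) > 1e-9:
            continue
        if (n_channels + 1) * round(spr) * 2 > 49152:
            continue
        best = d
    if best is None:
        raise ValueError(f"no EDF record duration fits fs={fs} with {n_channels} channels")
    return best


def write_edf(recording: ContinuousRecording, path: str | Path,
              event_label: str = EVENT_LABEL) -> None:
    """Write a recording as EDF+C with stimulus-onset annotations."""
    path = Path(path)
    data = np.asarray(recording.data, dtype=np.float64)
    n_ch, n_samp = data.shape
    fs = recording.fs_hz
    rec_dur = _pick_record_duration(fs, n_ch)
    spr = int(round(fs * rec_dur))
    n_records = math.ceil(n_samp / spr)

    # physical scaling: symmetric range per channel, 16-bit digital
    pmax = np.maximum(np.abs(data).max(axis=1), 1e-6)
    dig_max, dig_min = 32767, -32768
    scaled = np.clip(
        np.round((data + pmax[:, None]) * (65535.0 / (2 * pmax[:, None]))) + dig_min,
        dig_min, dig_max).astype("<i2")

    # annotation payload per record; each event assigned to exactly one record
    onsets_s = recording.events / fs
    rec_of_event = np.minimum((recording.events // int(round(fs * rec_dur))),
                              n_records - 1)
    tals: list[bytes] = []
    for r in range(n_records):
        tal = f"+{r * rec_dur:.6f}\x14\x14\x00".encode("ascii")
        for t in onsets_s[rec_of_event == r]:
            tal += f"+{t:.6f}\x14{event_label}\x14\x00".encode("ascii")
        tals.append(tal)
    ann_bytes = max(len(t) for t in tals)
    ann_spr = math.ceil(ann_bytes / 2) + 1  # 2-byte "samples", spare room

    n_signals = n_ch + 1
    header_bytes = 256 * (1 + n_signals)
    with open(path, "wb") as f:
        f.write(_ascii("0", 8))
        f.write(_ascii("X X X X", 80))                      # patient id
        f.write(_ascii("Startdate 01-JAN-2000 X X X", 80))  # recording id
        f.write(_ascii("01.01.00", 8))
        f.write(_ascii("00.00.00", 8))
        f.write(_ascii(header_bytes, 8))
        f.write(_ascii("EDF+C", 44))
        f.write(_ascii(n_records, 8))
        f.write(_ascii(f"{rec_dur:g}", 8))
        f.write(_ascii(n_signals, 4))

        labels = list(recording.channel_names) + ["EDF Annotations"]
        for lab in labels:
            f.write(_ascii(lab[:16], 16))
        for _ in labels:
            f.write(_ascii("", 80))                          # transducer
        for i in range(n_signals):
            f.write(_ascii("uV" if i < n_ch else "", 8))
        for i in range(n_signals):
            f.write(_ascii(_num8(-pmax[i]) if i < n_ch else -1, 8))
        for i in range(n_signals):
            f.write(_ascii(_num8(pmax[i]) if i < n_ch else 1, 8))
        for _ in range(n_signals):
            f.write(_ascii(dig_min, 8))
        for _ in range(n_signals):
            f.write(_ascii(dig_max, 8))
        for _ in range(n_signals):
            f.write(_ascii("", 80))                          # prefiltering
        for i in range(n_signals):
            f.write(_ascii(spr if i < n_ch else ann_spr, 8))
        for _ in range(n_signals):
            f.write(_ascii("", 32))                          # reserved

        pad = np.zeros((n_ch, n_records * spr - n_samp), dtype="<i2")
        full = np.concatenate([scaled, pad], axis=1)
        for r in range(n_records):
            f.write(full[:, r * spr:(r + 1) * spr].tobytes())
            ann = tals[r].ljust(ann_spr * 2, b"\x00")
            f.write(ann)


def read_edf(path: str | Path, event_label: str = EVENT_LABEL,
             reference: str = "unknown") -> ContinuousRecording:
    """Read an EDF/EDF+ file into a ContinuousRecording (data in uV).

    Stimulus onsets are taken from annotations whose description equals
    ``event_label``; pass ``reference`` to record how the data were
    referenced (EDF does not carry that information).
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data(units="uV")
    fs = float(raw.info["sfreq"])
    onsets = [a["onset"] for a in raw.annotations if a["description"] == event_label]
    events = np.round(np.asarray(onsets) * fs).astype(np.int64)
    events = events[events < data.shape[1]]
    return ContinuousRecording(data, fs, events, tuple(raw.ch_names), reference)
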