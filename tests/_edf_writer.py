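"""Minimal EDF+C writer for synthetic test fixtures.

Writes just enough of the EDF+ specification (ASCII header, int16 data
records, one 'EDF Annotations' channel carrying TAL-encoded event markers)
for mne's EDF reader to round-trip channel data and annotations. Test-only
helper; all data written with it is synthetic.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    assert len(b) <= width, f"{text!r} too long for {width}"
    return b.ljust(width)


def write_edf(
    path: str | Path,
    data: np.ndarray,
    sfreq: float,
    ch_names: list[str],
    annotations: list[tuple[float, float, str]] = (),
    record_seconds: float = 1.0,
) -> None:
    """Write (C, N) float data plus (onset, duration, text) annotations."""
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    assert len(ch_names) == n_ch
    spr = int(round(sfreq * record_seconds))  # samples per record per channel
    n_rec = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = data

    # digital/physical scaling per channel
    pmax = np.maximum(np.abs(padded).max(axis=1), 1e-9)
    dig_max, dig_min = 32767, -32768
    ann_bytes_per_rec = 60  # annotation channel size in 2-byte samples

    tal_per_record = []
    remaining = sorted(annotations, key=lambda a: a[0])
    for r in range(n_rec):
        t0 = r * record_seconds
        tal = f"+{t0:g}\x14\x14\x00".encode("ascii")  # record timestamp
        for onset, dur, text in remaining:
            if t0 <= onset < t0 + record_seconds:
                tal += f"+{onset:g}\x15{dur:g}\x14{text}\x14\x00".encode("ascii")
        assert len(tal) <= 2 * ann_bytes_per_rec, "too many annotations in one record"
        tal_per_record.append(tal.ljust(2 * ann_bytes_per_rec, b"\x00"))

    total_ch = n_ch + 1  # + annotations channel
    header_bytes = 256 * (1 + total_ch)
    with open(path, "wb") as fh:
        fh.write(_field("0", 8))
        fh.write(_field("X X X X", 80))                     # patient id
        fh.write(_field("Startdate 01-JAN-2020 X X X", 80))  # recording id
        fh.write(_field("01.01.20", 8))
        fh.write(_field("00.00.00", 8))
        fh.write(_field(str(header_bytes), 8))
        fh.write(_field("EDF+C", 44))
        fh.write(_field(str(n_rec), 8))
        fh.write(_field(f"{record_seconds:g}", 8))
        fh.write(_field(str(total_ch), 4))
        for name in ch_names:
            fh.write(_field(name, 16))
        fh.write(_field("EDF Annotations", 16))
        for _ in range(total_ch):
            fh.write(_field("", 80))                         # transducer
        for _ in range(n_ch):
            fh.write(_field("uV", 8))
        fh.write(_field("", 8))
        for p in pmax:
            fh.write(_field(f"{-p:.4g}", 8))
        fh.write(_field("-1", 8))
        for p in pmax:
            fh.write(_field(f"{p:.4g}", 8))
        fh.write(_field("1", 8))
        for _ in range(n_ch):
            fh.write(_field(str(dig_min), 8))
        fh.write(_field(str(dig_min), 8))
        for _ in range(n_ch):
            fh.write(_field(str(dig_max), 8))
        fh.write(_field(str(dig_max), 8))
        for _ in range(total_ch):
            fh.write(_field("", 80))                         # prefiltering
        for _ in range(n_ch):
            fh.write(_field(str(spr), 8))
        fh.write(_field(str(ann_bytes_per_rec), 8))
        for _ in range(total_ch):
            fh.write(_field("", 32))                         # reserved

        scale = pmax / dig_max
        for r in range(n_rec):
            chunk = padded[:, r * spr : (r + 1) * spr]
            dig = np.round(chunk / scale[:, None]).astype("<i2")
            fh.write(dig.tobytes())
            fh.write(tal_per_record[r])
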