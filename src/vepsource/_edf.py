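"""Minimal plain-EDF reader/writer for continuous multichannel recordings.

Implements the subset of the European Data Format this package needs: one
data-record duration of 1 s, 16-bit samples, identical sampling rate on every
signal, no annotation channel.  The true sample count is stored in the 44-byte
reserved header field as ``NSAMP=<n>`` because EDF pads the last record; a
reader that ignores the field simply sees edge-padded samples.

Values survive a round trip to within one 16-bit quantization step of the
per-channel physical range.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def quantization_step(data: np.ndarray) -> np.ndarray:
    """Per-channel physical quantization step used by :func:`write_edf`."""
    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    return 2.0 * phys_max / (2 * 32767)


def write_edf(path: str | Path, data: np.ndarray, fs: float,
              channel_names: list[str], physical_dim: str = "uV") -> None:
    """Write a channels-by-samples float array as 16-bit EDF."""
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    if len(channel_names) != n_ch:
        raise ValueError("channel_names must match the data row count")
    fs_int = int(round(fs))
    if abs(fs - fs_int) > 1e-9:
        raise ValueError("only integer sampling rates are supported")
    n_rec = int(np.ceil(n_samp / fs_int))
    pad = n_rec * fs_int - n_samp
    if pad:
        data = np.concatenate([data, np.repeat(data[:, -1:], pad, axis=1)],
                              axis=1)

    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((data - phys_min[:, None]) / scale[:, None]
                       + dig_min).astype("<i2")

    def f(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header = b"".join([
        f("0", 8),                       # version
        f("X X X X", 80),                # patient id
        f("Startdate X X X X", 80),      # recording id
        f("01.01.00", 8), f("00.00.00", 8),
        f(str(256 + 256 * n_ch), 8),     # header length
        f(f"NSAMP={n_samp}", 44),        # reserved: true sample count
        f(str(n_rec), 8),
        f("1", 8),                       # record duration, s
        f(str(n_ch), 4),
    ])
    header += b"".join(f(name, 16) for name in channel_names)
    header += b"".join(f("EEG", 80) for _ in range(n_ch))
    header += b"".join(f(physical_dim, 8) for _ in range(n_ch))
    header += b"".join(f(f"{v:.6g}", 8) for v in phys_min)
    header += b"".join(f(f"{v:.6g}", 8) for v in phys_max)
    header += b"".join(f(str(dig_min), 8) for _ in range(n_ch))
    header += b"".join(f(str(dig_max), 8) for _ in range(n_ch))
    header += b"".join(f("", 80) for _ in range(n_ch))      # prefiltering
    header += b"".join(f(str(fs_int), 8) for _ in range(n_ch))
    header += b"".join(f("", 32) for _ in range(n_ch))      # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        # records: per record, all samples of ch1, then ch2, ...
        rec = digital.reshape(n_ch, n_rec, fs_int)
        fh.write(np.ascontiguousarray(
            rec.transpose(1, 0, 2)).tobytes())


def read_edf(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file written by :func:`write_edf` (or any plain EDF with a
    uniform rate and no annotations).  Returns (data, fs, channel_names)."""
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise IOError("not an EDF file: header truncated")

    def s(lo: int, hi: int) -> str:
        return raw[lo:hi].decode("ascii", errors="replace").strip()

    n_rec = int(s(236, 244))
    rec_dur = float(s(244, 252))
    n_ch = int(s(252, 256))
    reserved = s(192, 236)
    off = 256
    names = [s(off + 16 * i, off + 16 * (i + 1)) for i in range(n_ch)]
    off += 16 * n_ch + 80 * n_ch + 8 * n_ch
    phys_min = np.array([float(s(off + 8 * i, off + 8 * (i + 1)))
                         for i in range(n_ch)])
    off += 8 * n_ch
    phys_max = np.array([float(s(off + 8 * i, off + 8 * (i + 1)))
                         for i in range(n_ch)])
    off += 8 * n_ch
    dig_min = np.array([int(s(off + 8 * i, off + 8 * (i + 1)))
                        for i in range(n_ch)])
    off += 8 * n_ch
    dig_max = np.array([int(s(off + 8 * i, off + 8 * (i + 1)))
                        for i in range(n_ch)])
    off += 8 * n_ch + 80 * n_ch
    spr = [int(s(off + 8 * i, off + 8 * (i + 1))) for i in range(n_ch)]
    if len(set(spr)) != 1:
        raise IOError("mixed per-signal sampling rates are not supported")
    header_len = int(s(184, 192))

    digital = np.frombuffer(raw, dtype="<i2", offset=header_len)
    digital = digital[:n_rec * n_ch * spr[0]].reshape(n_rec, n_ch, spr[0])
    data = digital.transpose(1, 0, 2).reshape(n_ch, -1).astype(float)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    data = (data - dig_min[:, None]) * scale[:, None] + phys_min[:, None]

    if reserved.startswith("NSAMP="):
        data = data[:, :int(reserved[6:])]
    fs = spr[0] / rec_dur
    return data, fs, names
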