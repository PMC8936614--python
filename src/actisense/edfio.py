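"""Minimal EDF (16-bit) / BDF (24-bit) continuous-recording reader and writer.

Supports exactly what the import path needs: one data record spanning the
whole recording, physical/digital scaling per channel, and channel labels.
Not a general-purpose EDF library.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_edf", "write_bdf", "read_raw"]


def _field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write(path, data: np.ndarray, fs: float, labels, kind: str) -> None:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be (n_samples, n_channels)")
    n_samples, n_ch = data.shape
    if len(labels) != n_ch:
        raise ValueError("label count must match channel count")
    if kind == "bdf":
        dig_min, dig_max, nbytes = -8388608, 8388607, 3
    else:
        dig_min, dig_max, nbytes = -32768, 32767, 2

    phys_min = data.min(axis=0)
    phys_max = data.max(axis=0)
    span = phys_max - phys_min
    flat = span <= 0
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    span = phys_max - phys_min
    # widen the physical range so the 8-character header fields, which
    # truncate to ~7 significant digits, still bracket every sample
    for _ in range(6):
        lo_ok = np.array([float(_field(f"{v:.7g}"[:8], 8).decode())
                          for v in phys_min]) <= data.min(axis=0)
        hi_ok = np.array([float(_field(f"{v:.7g}"[:8], 8).decode())
                          for v in phys_max]) >= data.max(axis=0)
        if lo_ok.all() and hi_ok.all():
            break
        phys_min = np.where(lo_ok, phys_min, phys_min - 1e-3 * span)
        phys_max = np.where(hi_ok, phys_max, phys_max + 1e-3 * span)

    duration = n_samples / fs
    header = bytearray()
    if kind == "bdf":
        header += b"\xffBIOSEMI"
    else:
        header += _field("0", 8)
    header += _field("synthetic", 80)
    header += _field("actisense export", 80)
    header += _field("01.01.20", 8)
    header += _field("00.00.00", 8)
    header += _field(256 * (1 + n_ch), 8)
    header += _field("24BIT" if kind == "bdf" else "", 44)
    header += _field(1, 8)                       # one data record
    header += _field(f"{duration:.6g}", 8)
    header += _field(n_ch, 4)
    for lab in labels:
        header += _field(lab, 16)
    for _ in range(n_ch):
        header += _field("synthetic", 80)
    for _ in range(n_ch):
        header += _field("uV", 8)
    for v in phys_min:
        header += _field(f"{v:.7g}"[:8], 8)
    for v in phys_max:
        header += _field(f"{v:.7g}"[:8], 8)
    for _ in range(n_ch):
        header += _field(dig_min, 8)
    for _ in range(n_ch):
        header += _field(dig_max, 8)
    for _ in range(n_ch):
        header += _field("", 80)
    for _ in range(n_ch):
        header += _field(n_samples, 8)
    for _ in range(n_ch):
        header += _field("", 32)

    # re-read the physical limits exactly as an importer will parse them, so
    # the digital scaling round-trips without quantization-offset surprises
    pmin = np.array([float(_field(f"{v:.7g}"[:8], 8).decode()) for v in phys_min])
    pmax = np.array([float(_field(f"{v:.7g}"[:8], 8).decode()) for v in phys_max])
    scale = (dig_max - dig_min) / (pmax - pmin)
    dig = np.round((data - pmin) * scale + dig_min).astype(np.int64)
    dig = np.clip(dig, dig_min, dig_max)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        sig = np.asfortranarray(dig)  # record layout: channel after channel
        for c in range(n_ch):
            col = sig[:, c]
            if nbytes == 2:
                fh.write(col.astype("<i2").tobytes())
            else:
                b = np.empty((n_samples, 3), dtype=np.uint8)
                u = col.astype(np.int64) & 0xFFFFFF
                b[:, 0] = u & 0xFF
                b[:, 1] = (u >> 8) & 0xFF
                b[:, 2] = (u >> 16) & 0xFF
                fh.write(b.tobytes())


def write_edf(path, data, fs, labels) -> None:
    _write(path, data, fs, labels, "edf")


def write_bdf(path, data, fs, labels) -> None:
    _write(path, data, fs, labels, "bdf")


def read_raw(path):
    """Read an EDF/BDF file written by this module (or compatible single/
    multi-record files); returns (data (n_samples, n_channels), fs, labels)."""
    with open(path, "rb") as fh:
        magic = fh.read(8)
        is_bdf = magic[0] == 0xFF
        fh.read(80 + 80 + 8 + 8)
        int(fh.read(8).decode().strip())  # header length
        fh.read(44)
        n_records = int(fh.read(8).decode().strip())
        rec_dur = float(fh.read(8).decode().strip())
        n_ch = int(fh.read(4).decode().strip())
        labels = [fh.read(16).decode().strip() for _ in range(n_ch)]
        fh.read(80 * n_ch + 8 * n_ch)
        pmin = np.array([float(fh.read(8).decode().strip()) for _ in range(n_ch)])
        pmax = np.array([float(fh.read(8).decode().strip()) for _ in range(n_ch)])
        dmin = np.array([int(fh.read(8).decode().strip()) for _ in range(n_ch)])
        dmax = np.array([int(fh.read(8).decode().strip()) for _ in range(n_ch)])
        fh.read(80 * n_ch)
        spr = [int(fh.read(8).decode().strip()) for _ in range(n_ch)]
        fh.read(32 * n_ch)
        if len(set(spr)) != 1:
            raise ValueError("heterogeneous per-channel rates are unsupported")
        nbytes = 3 if is_bdf else 2
        chunks = []
        for _ in range(n_records):
            rec = np.empty((spr[0], n_ch), dtype=np.int64)
            for c in range(n_ch):
                raw = fh.read(spr[c] * nbytes)
                if len(raw) < spr[c] * nbytes:
                    raise ValueError("truncated EDF/BDF data section")
                if nbytes == 2:
                    rec[:, c] = np.frombuffer(raw, dtype="<i2").astype(np.int64)
                else:
                    b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 3).astype(np.int64)
                    u = b[:, 0] | (b[:, 1] << 8) | (b[:, 2] << 16)
                    rec[:, c] = np.where(u >= 1 << 23, u - (1 << 24), u)
            chunks.append(rec)
    dig = np.vstack(chunks)
    scale = (pmax - pmin) / (dmax - dmin)
    data = (dig - dmin[None, :]) * scale[None, :] + pmin[None, :]
    fs = dig.shape[0] / (n_records * rec_dur)
    return data, fs, labels
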