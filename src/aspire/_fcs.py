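"""Minimal reader/writer for list-mode FCS 3.0/3.1 files.

Supports the common case produced by acquisition software and used
throughout cytometry pipelines: list-mode (``$MODE L``) data with float
(``$DATATYPE F``/``D``) or integer (``I``) events, little- or big-endian
byte order, channel short names from ``$PnN``.  The writer emits
little-endian float32 list-mode FCS 3.1, which this reader (and standard
parsers) can round-trip.
"""

from __future__ import annotations

import struct

import numpy as np


def read_fcs(path: str) -> tuple[np.ndarray, list[str]]:
    """Read one FCS file; returns (events x channels array, channel names)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 58:
        raise ValueError(f"{path}: truncated FCS header")
    version = raw[:6].decode("ascii", "replace")
    if not version.startswith("FCS"):
        raise ValueError(f"{path}: not an FCS file (version field {version!r})")
    try:
        text_start = int(raw[10:18])
        text_end = int(raw[18:26])
        data_start = int(raw[26:34])
        data_end = int(raw[34:42])
    except ValueError as exc:
        raise ValueError(f"{path}: malformed FCS header offsets") from exc
    text = raw[text_start:text_end + 1].decode("utf-8", "replace")
    delim = text[0]
    fields = text[1:].split(delim)
    kw = {fields[i].strip().upper(): fields[i + 1]
          for i in range(0, len(fields) - 1, 2)}
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    dtype_code = kw.get("$DATATYPE", "F").strip().upper()
    byteord = kw.get("$BYTEORD", "1,2,3,4").strip()
    little = byteord.startswith("1")
    if data_start == 0 and "$BEGINDATA" in kw:
        data_start = int(kw["$BEGINDATA"])
        data_end = int(kw["$ENDDATA"])
    channels = []
    bits = []
    for p in range(1, n_par + 1):
        channels.append(kw.get(f"$P{p}N", f"ch{p - 1}").strip())
        bits.append(int(kw.get(f"$P{p}B", "32")))
    if dtype_code == "F":
        np_dtype = "<f4" if little else ">f4"
    elif dtype_code == "D":
        np_dtype = "<f8" if little else ">f8"
    elif dtype_code == "I":
        nbytes = bits[0] // 8
        if any(b != bits[0] for b in bits):
            raise ValueError(f"{path}: mixed integer widths are not supported")
        np_dtype = ("<" if little else ">") + f"u{nbytes}"
    else:
        raise ValueError(f"{path}: unsupported $DATATYPE {dtype_code!r}")
    buf = raw[data_start:data_end + 1]
    data = np.frombuffer(buf, dtype=np_dtype, count=n_par * n_tot)
    return data.reshape(n_tot, n_par).astype(np.float64), channels


def write_fcs(path: str, data: np.ndarray, channels: list[str]) -> None:
    """Write events as little-endian float32 list-mode FCS 3.1."""
    data = np.asarray(data, dtype=np.float32)
    n_tot, n_par = data.shape
    if len(channels) != n_par:
        raise ValueError("channel count does not match data columns")
    delim = "/"
    kw = {
        "$MODE": "L", "$DATATYPE": "F", "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par), "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for p, name in enumerate(channels, start=1):
        kw[f"$P{p}N"] = str(name)
        kw[f"$P{p}B"] = "32"
        kw[f"$P{p}E"] = "0,0"
        kw[f"$P{p}R"] = str(int(np.ceil(float(np.abs(data).max() + 1))))
    # two-pass layout: text segment length depends on the data offsets
    header_len = 58
    body = data.tobytes()
    for _ in range(3):
        text = delim + delim.join(f"{k}{delim}{v}" for k, v in
                                  sorted(kw.items()))
        text_start = header_len
        text_end = text_start + len(text) - 1
        data_start = text_end + 1
        data_end = data_start + len(body) - 1
        kw["$BEGINDATA"] = str(data_start)
        kw["$ENDDATA"] = str(data_end)
    header = (b"FCS3.1    "
              + f"{text_start:8d}".encode()
              + f"{text_end:8d}".encode()
              + (f"{data_start:8d}".encode() if data_start <= 99_999_999
                 else b"       0")
              + (f"{data_end:8d}".encode() if data_end <= 99_999_999
                 else b"       0")
              + b"       0" + b"       0")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text.encode("utf-8"))
        fh.write(body)
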