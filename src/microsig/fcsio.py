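"""Minimal FCS 3.1 reader/writer for LIST-mode floating-point event data.

Covers the subset of the standard this package produces and consumes:
one dataset per file, ``$MODE L``, ``$DATATYPE F`` (or ``D`` on read),
little- or big-endian ``$BYTEORD``. Keyword values are stored in the
primary TEXT segment with ``/`` as delimiter.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

_DELIM = "/"
_TEXT_START = 256  # fixed offset of the primary TEXT segment when writing


class FCSFormatError(ValueError):
    """File does not parse as the supported FCS subset."""


def write_fcs(path: str | Path, channel_names: list[str],
              data: np.ndarray) -> None:
    """Write events as FCS 3.1, float32 LIST mode, little-endian."""
    data = np.ascontiguousarray(np.asarray(data, dtype=np.float32))
    n_events, n_par = data.shape
    if n_par != len(channel_names):
        raise ValueError("channel_names length must match data width")
    nbytes = data.size * 4

    def build_text(begin_data: int, end_data: int) -> bytes:
        kw = {
            "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
            "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
            "$BEGINDATA": f"{begin_data:012d}", "$ENDDATA": f"{end_data:012d}",
            "$BYTEORD": "1,2,3,4", "$DATATYPE": "F", "$MODE": "L",
            "$NEXTDATA": "0", "$PAR": str(n_par), "$TOT": str(n_events),
        }
        for i, name in enumerate(channel_names, start=1):
            kw[f"$P{i}N"] = name
            kw[f"$P{i}B"] = "32"
            kw[f"$P{i}E"] = "0,0"
            kw[f"$P{i}R"] = str(int(float(data[:, i - 1].max())) + 1
                                if n_events else 1)
        parts = [_DELIM]
        for k, v in kw.items():
            parts.append(f"{k}{_DELIM}{v}{_DELIM}")
        return "".join(parts).encode("ascii")

    # fixed-width offsets keep the TEXT length independent of their values
    text = build_text(0, 0)
    begin_data = _TEXT_START + len(text)
    end_data = begin_data + nbytes - 1
    text = build_text(begin_data, end_data)
    text_end = _TEXT_START + len(text) - 1

    header = (b"FCS3.1    "
              + f"{_TEXT_START:8d}".encode()
              + f"{text_end:8d}".encode()
              + (f"{begin_data:8d}".encode() if begin_data <= 99_999_999
                 else b"       0")
              + (f"{end_data:8d}".encode() if end_data <= 99_999_999
                 else b"       0")
              + b"       0" + b"       0")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b" " * (_TEXT_START - len(header)))
        fh.write(text)
        fh.write(data.astype("<f4").tobytes())


def _parse_text(raw: bytes) -> dict[str, str]:
    txt = raw.decode("ascii", errors="replace")
    delim = txt[0]
    fields = txt[1:].split(delim)
    if fields and fields[-1] == "":
        fields = fields[:-1]
    if len(fields) % 2:
        fields = fields[:-1]
    return {fields[i].strip(): fields[i + 1] for i in range(0, len(fields), 2)}


def read_fcs(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read an FCS 3.0/3.1 LIST-mode file; returns (channel names, events)."""
    blob = Path(path).read_bytes()
    if len(blob) < 58 or not blob[:3] == b"FCS":
        raise FCSFormatError("not an FCS file")
    try:
        text_begin = int(blob[10:18])
        text_end = int(blob[18:26])
    except ValueError as exc:
        raise FCSFormatError("unreadable header offsets") from exc
    if text_end >= len(blob):
        raise FCSFormatError("truncated file: TEXT segment out of range")
    kw = _parse_text(blob[text_begin:text_end + 1])

    mode = kw.get("$MODE", "L")
    if mode != "L":
        raise FCSFormatError(f"unsupported $MODE {mode!r}")
    dtype_code = kw.get("$DATATYPE", "F")
    if dtype_code not in ("F", "D"):
        raise FCSFormatError(f"unsupported $DATATYPE {dtype_code!r}")
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    itemsize = 4 if dtype_code == "F" else 8
    np_dtype = np.dtype(f"{endian}f{itemsize}")

    begin_data = int(kw.get("$BEGINDATA", "0") or 0)
    end_data = int(kw.get("$ENDDATA", "0") or 0)
    if begin_data == 0:
        begin_data = int(blob[26:34])
        end_data = int(blob[34:42])
    nbytes = n_par * n_tot * itemsize
    if begin_data + nbytes > len(blob):
        raise FCSFormatError("truncated file: DATA segment out of range")
    if end_data and end_data - begin_data + 1 != nbytes:
        raise FCSFormatError("DATA segment size disagrees with $PAR*$TOT")

    names = []
    for i in range(1, n_par + 1):
        name = kw.get(f"$P{i}N") or kw.get(f"$P{i}S") or f"P{i}"
        names.append(name)
        bits = kw.get(f"$P{i}B", str(itemsize * 8))
        if bits != str(itemsize * 8):
            raise FCSFormatError(f"unsupported $P{i}B={bits} for {dtype_code}")
    data = np.frombuffer(blob, dtype=np_dtype, count=n_par * n_tot,
                         offset=begin_data).reshape(n_tot, n_par)
    return names, data.astype(float)
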