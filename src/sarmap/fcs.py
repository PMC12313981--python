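"""Minimal FCS 3.1 reader/writer.

Supports the subset of the standard that list-mode float data needs:
``$DATATYPE/F`` (IEEE float32), ``$MODE/L``, little- or big-endian
``$BYTEORD``, and a single data segment. Integer data types, analysis
segments, and multi-dataset files are out of scope; files are written as
FCS 3.1 with a float32 data segment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import SarmapError

_DELIM = "/"
_HEADER_LEN = 58


class FCSFormatError(SarmapError):
    """File does not parse as supported FCS."""


def write_fcs(path, data: pd.DataFrame, extra_keywords: dict | None = None) -> None:
    """Write a numeric events-by-channels DataFrame as FCS 3.1 float32.

    Column names become ``$PnN`` short channel names. ``extra_keywords``
    are merged into the TEXT segment (values are stringified).
    """
    values = np.ascontiguousarray(data.to_numpy(dtype="<f4"))
    n_events, n_par = values.shape
    keywords = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$TOT": str(n_events),
        "$PAR": str(n_par),
    }
    for i, name in enumerate(data.columns, start=1):
        keywords[f"$P{i}N"] = str(name)
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(int(max(1.0, float(np.nanmax(values[:, i - 1])) + 1.0)) if n_events else 1)
    if extra_keywords:
        keywords.update({str(k): str(v) for k, v in extra_keywords.items()})

    data_size = values.nbytes

    # any single ASCII byte may delimit the TEXT segment; pick one that no
    # keyword or value contains (channel names like "p-S6 S240/244" rule
    # out the conventional "/")
    tokens = [str(t) for kv in keywords.items() for t in kv]
    for delim in (_DELIM, "|", "\x0c", "\x1e", "\x1f"):
        if not any(delim in t for t in tokens):
            break
    else:
        raise FCSFormatError("no usable TEXT delimiter for these keywords")

    def render_text(begin_data: int, end_data: int) -> bytes:
        kw = dict(keywords)
        kw["$BEGINDATA"] = str(begin_data)
        kw["$ENDDATA"] = str(end_data)
        parts = [delim]
        for k, v in kw.items():
            parts.append(f"{k}{delim}{v}{delim}")
        return "".join(parts).encode("utf-8")

    # TEXT length depends on the data offsets it declares; iterate to fixpoint.
    text_start = _HEADER_LEN
    begin_data = 0
    for _ in range(8):
        text = render_text(begin_data, begin_data + data_size - 1 if data_size else 0)
        new_begin = text_start + len(text)
        if new_begin == begin_data:
            break
        begin_data = new_begin
    text = render_text(begin_data, begin_data + data_size - 1 if data_size else 0)
    text_end = text_start + len(text) - 1
    end_data = begin_data + data_size - 1 if data_size else 0

    def offset_field(v: int) -> bytes:
        s = str(v)
        if len(s) > 8:
            s = "0"  # too large for the header; TEXT keywords carry the truth
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    "
    header += offset_field(text_start) + offset_field(text_end)
    header += offset_field(begin_data if end_data <= 99999999 else 0)
    header += offset_field(end_data if end_data <= 99999999 else 0)
    header += offset_field(0) + offset_field(0)
    assert len(header) == _HEADER_LEN

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(values.tobytes())


def read_fcs(path) -> tuple[pd.DataFrame, dict]:
    """Read an FCS 3.0/3.1 float list-mode file.

    Returns ``(data, keywords)`` where ``data`` is an events-by-channels
    DataFrame with ``$PnN`` column names.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < _HEADER_LEN or not raw[:6] in (b"FCS3.0", b"FCS3.1"):
        raise FCSFormatError(f"{path}: not an FCS 3.x file")

    def header_offset(a: int, b: int) -> int:
        field = raw[a:b].decode("ascii", "replace").strip()
        return int(field) if field else 0

    text_start = header_offset(10, 18)
    text_end = header_offset(18, 26)
    text = raw[text_start : text_end + 1].decode("utf-8", "replace")
    if not text:
        raise FCSFormatError(f"{path}: empty TEXT segment")
    delim = text[0]
    fields = text[1:].split(delim)
    if fields and fields[-1] == "":
        fields = fields[:-1]
    if len(fields) % 2:
        raise FCSFormatError(f"{path}: malformed TEXT segment")
    keywords = {fields[i].strip(): fields[i + 1] for i in range(0, len(fields), 2)}

    n_par = int(keywords["$PAR"])
    n_tot = int(keywords["$TOT"])
    datatype = keywords.get("$DATATYPE", "F").upper()
    if datatype != "F":
        raise FCSFormatError(f"{path}: unsupported $DATATYPE {datatype!r} (float only)")
    byteord = keywords.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"

    begin_data = int(keywords.get("$BEGINDATA") or header_offset(26, 34))
    end_data = int(keywords.get("$ENDDATA") or header_offset(34, 42))
    n_bytes = n_par * n_tot * 4
    if end_data and end_data - begin_data + 1 < n_bytes:
        raise FCSFormatError(f"{path}: data segment shorter than $PAR x $TOT")
    values = np.frombuffer(raw, dtype=f"{endian}f4", count=n_par * n_tot, offset=begin_data)
    values = values.reshape(n_tot, n_par)
    names = [keywords.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    return pd.DataFrame(values.copy(), columns=names), keywords
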