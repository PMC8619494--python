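"""Minimal FCS 3.0/3.1 list-mode reader and writer.

Covers the subset of the FCS standard that cytometer export files for
scatter-based assays actually use: a single dataset, list-mode (``$MODE L``)
data in float32 (``$DATATYPE F``), float64 (``D``) or unsigned integer
(``I``, 16- or 32-bit) encoding, little- or big-endian byte order. Spillover
matrices, analysis segments and multi-dataset files are out of scope.

The writer emits FCS 3.1 float32 little-endian files, which round-trip
through this reader and through common third-party FCS tools.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

_HEADER_LEN = 58

_DTYPES = {
    ("F", 32): "f4",
    ("D", 64): "f8",
    ("I", 16): "u2",
    ("I", 32): "u4",
}


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FormatError("empty TEXT segment")
    delim = raw[0:1]
    # A doubled delimiter escapes a literal delimiter inside a value; the
    # files this package writes and reads never need that, so a plain split
    # with empty-token coalescing is sufficient.
    tokens = raw[1:].split(delim)
    if tokens and tokens[-1] == b"":
        tokens = tokens[:-1]
    if len(tokens) % 2:
        raise FormatError("TEXT segment has an odd number of key/value tokens")
    out: dict[str, str] = {}
    for key, val in zip(tokens[::2], tokens[1::2]):
        out[key.decode("utf-8", "replace").strip().upper()] = val.decode(
            "utf-8", "replace"
        )
    return out


def read_fcs(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read an FCS file; return (events DataFrame, TEXT keywords).

    Columns are named after ``$PnN``. Event order is preserved.
    """
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < _HEADER_LEN:
        raise FormatError(f"{path}: file shorter than an FCS header")
    version = blob[:6].decode("ascii", "replace")
    if not version.startswith("FCS"):
        raise FormatError(f"{path}: not an FCS file (magic {version!r})")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FormatError(f"{path}: unsupported FCS version {version!r}")

    def _offset(field: bytes) -> int:
        txt = field.decode("ascii", "replace").strip()
        return int(txt) if txt else 0

    text_begin = _offset(blob[10:18])
    text_end = _offset(blob[18:26])
    data_begin = _offset(blob[26:34])
    data_end = _offset(blob[34:42])
    if text_end <= text_begin:
        raise FormatError(f"{path}: invalid TEXT segment offsets")
    text = _parse_text_segment(blob[text_begin : text_end + 1])

    if data_begin == 0 or data_end == 0:  # FCS 3.x: may live only in TEXT
        data_begin = int(text.get("$BEGINDATA", 0))
        data_end = int(text.get("$ENDDATA", 0))
    if data_end <= data_begin:
        raise FormatError(f"{path}: invalid DATA segment offsets")

    mode = text.get("$MODE", "L").upper()
    if mode != "L":
        raise FormatError(f"{path}: only list-mode ($MODE L) supported, got {mode!r}")
    datatype = text.get("$DATATYPE", "").upper()
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    bits = {int(text[f"$P{i}B"]) for i in range(1, n_par + 1)}
    if len(bits) != 1:
        raise FormatError(f"{path}: mixed per-parameter bit widths unsupported")
    key = (datatype, bits.pop())
    if key not in _DTYPES:
        raise FormatError(f"{path}: unsupported $DATATYPE/$PnB combination {key}")
    byteord = text.get("$BYTEORD", "1,2,3,4").strip()
    endian = "<" if byteord.startswith("1") else ">"
    dtype = np.dtype(endian + _DTYPES[key])

    raw = blob[data_begin : data_end + 1]
    expect = n_par * n_tot * dtype.itemsize
    if len(raw) < expect:
        raise FormatError(
            f"{path}: truncated DATA segment ({len(raw)} bytes, expected {expect})"
        )
    values = np.frombuffer(raw[:expect], dtype=dtype).reshape(n_tot, n_par)
    names = [text.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    frame = pd.DataFrame(np.asarray(values, dtype=np.float64), columns=names)
    return frame, text


def write_fcs(
    path: str | Path,
    events: pd.DataFrame,
    extra_keywords: dict[str, str] | None = None,
) -> None:
    """Write events as a single-dataset FCS 3.1 float32 little-endian file."""
    path = Path(path)
    data = np.ascontiguousarray(events.to_numpy(dtype="<f4"))
    n_tot, n_par = data.shape
    ranges = data.max(axis=0) if n_tot else np.ones(n_par)

    kw: dict[str, str] = {
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
    }
    for i, name in enumerate(events.columns, start=1):
        kw[f"$P{i}N"] = str(name)
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = str(int(np.ceil(ranges[i - 1])) + 1)
    if extra_keywords:
        kw.update({str(k): str(v) for k, v in extra_keywords.items()})

    delim = "/"
    # DATA offsets appear inside TEXT, so reserve fixed-width placeholders,
    # lay the file out, then substitute the real offsets.
    placeholder = {"$BEGINDATA": "0" * 12, "$ENDDATA": "0" * 12}

    def render(text_kw: dict[str, str]) -> bytes:
        parts = [delim]
        for k, v in text_kw.items():
            parts.append(f"{k}{delim}{v if v != '' else ' '}{delim}")
        return "".join(parts).encode("ascii")

    text = render({**kw, **placeholder})
    text_begin = _HEADER_LEN
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + data.nbytes - 1 if n_tot else data_begin

    filled = render(
        {**kw, "$BEGINDATA": f"{data_begin:012d}", "$ENDDATA": f"{data_end:012d}"}
    )
    assert len(filled) == len(text)

    def fmt(n: int) -> bytes:
        s = str(n)
        if len(s) > 8:  # too large for the header field; TEXT carries it
            s = "0"
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1" + b" " * 4
    header += fmt(text_begin) + fmt(text_end)
    header += fmt(data_begin) + fmt(data_end)
    header += fmt(0) + fmt(0)
    assert len(header) == _HEADER_LEN, len(header)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(filled)
        fh.write(data.tobytes())
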