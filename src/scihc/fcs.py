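"""Minimal FCS 3.1 writer/reader for image-cytometry tables.

Writes the per-cell table (X/Y coordinates in microns plus one
parameter per marker) as a standard list-mode FCS 3.1 file —
little-endian single-precision floats, ``$DATATYPE/F``, ``$MODE/L`` —
so the output imports into any flow-cytometry analysis application.
The reader supports exactly what the writer emits plus common
variations (big-endian, double precision) and exists so round-trips
are verifiable in-repo.

Parameter names are sanitized to alphanumerics/underscore in ``$PnN``;
the original name is preserved in ``$PnS``.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

_DELIM = "/"


def sanitize_name(name: str) -> str:
    out = re.sub(r"[^A-Za-z0-9_-]", "_", name)
    return out or "_"


def _text_segment(pairs: list[tuple[str, str]]) -> bytes:
    parts = [_DELIM]
    for k, v in pairs:
        parts.append(f"{k}{_DELIM}{v}{_DELIM}")
    return "".join(parts).encode("ascii")


def write_fcs(path, data: pd.DataFrame | np.ndarray, names: list[str] | None = None) -> None:
    """Write events x parameters as FCS 3.1 (little-endian float32).

    ``data`` may be a DataFrame (column names become parameters) or a
    2-D array with ``names``. Raises on an empty table.
    """
    if isinstance(data, pd.DataFrame):
        names = [str(c) for c in data.columns]
        values = data.to_numpy(dtype=np.float32)
    else:
        values = np.asarray(data, dtype=np.float32)
        if names is None:
            raise ValueError("names required when data is an array")
    if values.ndim != 2 or values.size == 0:
        raise ValueError("cannot write an empty FCS table")
    n_events, n_par = values.shape
    if len(names) != n_par:
        raise ValueError("names/columns mismatch")

    raw = values.astype("<f4").tobytes()
    pairs = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$TOT", str(n_events)),
        ("$PAR", str(n_par)),
    ]
    for i, name in enumerate(names, start=1):
        rng = float(np.nanmax(values[:, i - 1])) if n_events else 0.0
        pairs += [
            (f"$P{i}N", sanitize_name(name)),
            (f"$P{i}S", name),
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}R", str(int(np.ceil(abs(rng))) + 1)),
        ]

    header_len = 58
    # offsets depend on the TEXT length, which depends on the offsets:
    # iterate until stable (converges in <= 3 passes)
    begin_data = end_data = 0
    for _ in range(5):
        text = _text_segment(
            pairs + [("$BEGINDATA", str(begin_data)), ("$ENDDATA", str(end_data))]
        )
        new_begin = header_len + len(text)
        new_end = new_begin + len(raw) - 1
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    text = _text_segment(
        pairs + [("$BEGINDATA", str(begin_data)), ("$ENDDATA", str(end_data))]
    )

    text_begin = header_len
    text_end = text_begin + len(text) - 1

    def hdr_field(v: int) -> bytes:
        s = str(v)
        if len(s) > 8:
            s = "0"  # too large for the header; TEXT keywords carry it
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    "  # 6-byte version + 4 spaces
    header += hdr_field(text_begin) + hdr_field(text_end)
    if end_data <= 99999999:
        header += hdr_field(begin_data) + hdr_field(end_data)
    else:
        header += hdr_field(0) + hdr_field(0)
    header += hdr_field(0) + hdr_field(0)  # no ANALYSIS segment
    assert len(header) == 58

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(raw)


def read_fcs(path) -> pd.DataFrame:
    """Parse an FCS file written by :func:`write_fcs` (and the common
    float-mode variants). Returns a DataFrame with ``$PnN`` columns."""
    with open(path, "rb") as fh:
        blob = fh.read()
    if not blob[:3] == b"FCS":
        raise ValueError("not an FCS file")
    text_begin = int(blob[10:18])
    text_end = int(blob[18:26])
    text = blob[text_begin : text_end + 1].decode("ascii", errors="replace")
    delim = text[0]
    tokens = text[1:].split(delim)
    kv: dict[str, str] = {}
    for k, v in zip(tokens[::2], tokens[1::2]):
        if k:
            kv[k.strip().upper()] = v
    n_par = int(kv["$PAR"])
    n_tot = int(kv["$TOT"])
    begin_data = int(kv.get("$BEGINDATA") or blob[26:34])
    dtype_code = kv.get("$DATATYPE", "F").upper()
    byteord = kv.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    if dtype_code == "F":
        dt = np.dtype(endian + "f4")
    elif dtype_code == "D":
        dt = np.dtype(endian + "f8")
    else:
        raise ValueError(f"unsupported $DATATYPE {dtype_code!r}")
    count = n_par * n_tot
    values = np.frombuffer(blob, dtype=dt, count=count, offset=begin_data)
    names = [kv.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    return pd.DataFrame(values.reshape(n_tot, n_par).astype(np.float64), columns=names)
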