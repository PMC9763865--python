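"""Minimal FCS 3.0/3.1 list-mode reader (and a writer used for testing).

Supports the subset of the standard needed for read-only ingestion of
event tables: list mode ($MODE L), float ($DATATYPE F/D) or integer
($DATATYPE I) data, little/big endian $BYTEORD, and log->linear
conversion of log-amplified parameters from $PnE/$PnR keywords
(``linear = f2 * 10**(f1 * raw / range)``, with ``f2 == 0`` read as 1
per common instrument convention).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyInputError

__all__ = ["read_fcs", "write_fcs"]

_DTYPES = {"F": "f4", "D": "f8", "I": "u"}


def _parse_text(raw: bytes) -> dict[str, str]:
    delim = raw[:1].decode("latin-1")
    parts = raw.decode("latin-1").strip(delim).split(delim)
    return {k.strip().upper(): v for k, v in zip(parts[::2], parts[1::2])}


def read_fcs(path, linearize: bool = True) -> pd.DataFrame:
    """Read an FCS file into a DataFrame of events (columns = $PnN)."""
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < 58:
        raise EmptyInputError(f"{path} is not a valid FCS file (too short)")
    version = blob[:6].decode("latin-1")
    if not version.startswith("FCS3"):
        raise ConfigError(f"unsupported FCS version {version!r}")
    text_start, text_end = int(blob[10:18]), int(blob[18:26])
    data_start, data_end = int(blob[26:34] or 0), int(blob[34:42] or 0)
    text = _parse_text(blob[text_start:text_end + 1])
    if data_start == 0:
        data_start = int(text["$BEGINDATA"])
        data_end = int(text["$ENDDATA"])

    if text.get("$MODE", "L").upper() != "L":
        raise ConfigError("only list mode ($MODE L) is supported")
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    datatype = text["$DATATYPE"].upper()
    byteord = text["$BYTEORD"]
    endian = "<" if byteord.startswith("1") else ">"
    if datatype in ("F", "D"):
        dtype = np.dtype(endian + _DTYPES[datatype])
        widths = [dtype.itemsize * 8] * n_par
    elif datatype == "I":
        widths = [int(text[f"$P{i}B"]) for i in range(1, n_par + 1)]
        if len(set(widths)) != 1 or widths[0] not in (8, 16, 32):
            raise ConfigError("only uniform 8/16/32-bit integer data supported")
        dtype = np.dtype(f"{endian}u{widths[0] // 8}")
    else:
        raise ConfigError(f"unsupported $DATATYPE {datatype!r}")

    data = np.frombuffer(blob[data_start:data_end + 1],
                         dtype=dtype, count=n_par * n_tot)
    data = data.reshape(n_tot, n_par).astype(float)

    names = [text.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    if linearize:
        for i in range(n_par):
            pne = text.get(f"$P{i + 1}E", "0,0")
            f1, f2 = (float(v) for v in pne.split(","))
            if f1 > 0:
                rng = float(text.get(f"$P{i + 1}R", 1024))
                data[:, i] = (f2 or 1.0) * 10.0 ** (f1 * data[:, i] / rng)
    return pd.DataFrame(data, columns=names)


def write_fcs(path, table: pd.DataFrame, pne: dict[str, str] | None = None,
              pnr: dict[str, float] | None = None) -> None:
    """Write a float32 FCS 3.1 file (testing/interoperability helper).

    ``pne`` maps column names to $PnE strings (e.g. ``"4,1"`` marks a
    channel as stored log-amplified over ``pnr`` decades' range); the
    stored values are the raw values from ``table``.
    """
    pne = pne or {}
    pnr = pnr or {}
    n_tot, n_par = table.shape
    data = np.ascontiguousarray(table.to_numpy(np.float32))
    kw = {
        "$MODE": "L", "$DATATYPE": "F", "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par), "$TOT": str(n_tot), "$NEXTDATA": "0",
    }
    for i, name in enumerate(table.columns, start=1):
        kw[f"$P{i}N"] = str(name)
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = pne.get(name, "0,0")
        kw[f"$P{i}R"] = str(pnr.get(name, 262144))

    header_len = 58
    # two-pass layout: sizes of BEGINDATA/ENDDATA values may shift offsets
    for _ in range(3):
        text = "/" + "".join(f"{k}/{v}/" for k, v in kw.items())
        data_start = header_len + len(text)
        data_end = data_start + data.nbytes - 1
        if kw.get("$BEGINDATA") == str(data_start):
            break
        kw["$BEGINDATA"] = str(data_start)
        kw["$ENDDATA"] = str(data_end)
    text_bytes = text.encode("latin-1")
    header = (b"FCS3.1    "
              + f"{header_len:>8d}".encode()
              + f"{header_len + len(text_bytes) - 1:>8d}".encode()
              + f"{data_start:>8d}".encode()
              + f"{data_end:>8d}".encode()
              + b"       0" + b"       0")
    assert len(header) == header_len
    Path(path).write_bytes(header + text_bytes + data.tobytes())
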