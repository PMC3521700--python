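"""Minimal FCS 3.1 reading and writing.

Flow Cytometry Standard files store a fixed-width ASCII HEADER with byte
offsets, a delimited TEXT segment of ``$KEYWORD/value`` pairs, and a DATA
segment.  This module supports the subset the pipeline needs: single-dataset,
list-mode files with float (``$DATATYPE F``, 32-bit) or integer
(``$DATATYPE I``) events, little- or big-endian.  It exists because the
analysis stack otherwise only consumes CSV event tables, and cytometer
exports are FCS.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import FcsFormatError

_DELIM = "/"
_VERSION = b"FCS3.1"


def write_fcs(path: str | Path, channels: dict[str, np.ndarray], *, extra_keywords: dict[str, str] | None = None) -> None:
    """Write a list-mode float32 FCS 3.1 file with one column per channel.

    Parameters
    ----------
    channels
        Mapping of channel short name (``$PnN``) to a 1-D array of per-event
        values.  All arrays must share one length.
    extra_keywords
        Additional TEXT keywords, e.g. ``{"$WELLID": "A03"}``.
    """
    names = list(channels)
    if not names:
        raise ValueError("at least one channel required")
    arrays = [np.asarray(channels[n], dtype="<f4") for n in names]
    n_events = len(arrays[0])
    if any(len(a) != n_events for a in arrays):
        raise ValueError("all channels must have the same number of events")

    data = np.column_stack(arrays).astype("<f4").tobytes()

    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(len(names)),
        "$TOT": str(n_events),
    }
    for i, (name, arr) in enumerate(zip(names, arrays), start=1):
        rng = float(arr.max(initial=0.0))
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}N"] = name
        keywords[f"$P{i}R"] = str(int(np.ceil(rng)) + 1)
    if extra_keywords:
        keywords.update(extra_keywords)

    # TEXT length depends on the data offsets it contains, so reserve fixed
    # 12-digit fields for them and fill in afterwards.
    def render(begin_data: int, end_data: int) -> bytes:
        kw = dict(keywords)
        kw["$BEGINDATA"] = f"{begin_data:012d}"
        kw["$ENDDATA"] = f"{end_data:012d}"
        parts = [_DELIM]
        for k, v in kw.items():
            parts.append(f"{k}{_DELIM}{v}{_DELIM}")
        return "".join(parts).encode("ascii")

    header_len = 58  # 6 version + 4 spaces + 6 fields of 8 chars
    text = render(0, 0)
    text_start = header_len
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + len(data) - 1
    text = render(data_start, data_end)
    if len(text) != text_end - text_start + 1:
        raise AssertionError("TEXT length changed while patching offsets")

    header = _VERSION + b"    "
    for off in (text_start, text_end, data_start, data_end, 0, 0):
        header += f"{off:>8d}".encode("ascii")

    Path(path).write_bytes(header + text + data)


def read_fcs(path: str | Path) -> tuple[dict[str, np.ndarray], dict[str, str]]:
    """Read an FCS 3.0/3.1 file; return (channel name -> values, TEXT keywords)."""
    raw = Path(path).read_bytes()
    if len(raw) < 58:
        raise FcsFormatError(f"{path}: file shorter than an FCS header")
    if not raw[:6] in (b"FCS3.0", b"FCS3.1"):
        raise FcsFormatError(f"{path}: not an FCS 3.0/3.1 file (magic {raw[:6]!r})")

    def offset(i: int) -> int:
        field = raw[10 + 8 * i : 18 + 8 * i].strip()
        try:
            return int(field)
        except ValueError as exc:
            raise FcsFormatError(f"{path}: malformed header offset {field!r}") from exc

    text_start, text_end = offset(0), offset(1)
    if text_end >= len(raw) or text_start >= text_end:
        raise FcsFormatError(f"{path}: TEXT segment offsets out of range")
    text = raw[text_start : text_end + 1].decode("ascii", errors="replace")
    delim = text[0]
    tokens = text[1:].split(delim)
    # Trailing delimiter yields an empty final token.
    if tokens and tokens[-1] == "":
        tokens = tokens[:-1]
    if len(tokens) % 2:
        raise FcsFormatError(f"{path}: odd number of TEXT tokens")
    keywords = {tokens[i].strip(): tokens[i + 1] for i in range(0, len(tokens), 2)}

    try:
        n_par = int(keywords["$PAR"])
        n_tot = int(keywords["$TOT"])
        datatype = keywords["$DATATYPE"].strip().upper()
        byteord = keywords["$BYTEORD"].strip()
    except KeyError as exc:
        raise FcsFormatError(f"{path}: missing required keyword {exc}") from exc

    data_start = offset(2) or int(keywords.get("$BEGINDATA", 0))
    data_end = offset(3) or int(keywords.get("$ENDDATA", 0))
    endian = "<" if byteord.startswith("1") else ">"
    if datatype == "F":
        dtype = np.dtype(f"{endian}f4")
    elif datatype == "D":
        dtype = np.dtype(f"{endian}f8")
    elif datatype == "I":
        bits = {int(keywords.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)}
        if len(bits) != 1:
            raise FcsFormatError(f"{path}: mixed integer widths unsupported")
        dtype = np.dtype(f"{endian}u{bits.pop() // 8}")
    else:
        raise FcsFormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

    expected = n_par * n_tot * dtype.itemsize
    segment = raw[data_start : data_end + 1]
    if len(segment) < expected:
        raise FcsFormatError(
            f"{path}: truncated DATA segment ({len(segment)} bytes, need {expected})"
        )
    values = np.frombuffer(segment[:expected], dtype=dtype).reshape(n_tot, n_par)

    names = [keywords.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    return {name: values[:, i].astype(float) for i, name in enumerate(names)}, keywords
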