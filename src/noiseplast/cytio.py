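"""Flow-cytometry event I/O and the canonical tabular data model.

Every stage of the pipeline operates on an *event table*: a pandas DataFrame
with one row per recorded cell and the columns

``strain_id, condition_id, replicate_id, batch_id, fsc, ssc, yfp_raw``

where the first four identify the clonal population (strain x condition x
biological replicate) and the measurement day (batch), and the last three are
linear-scale instrument channels (forward scatter, side scatter, raw yellow
fluorescence) in arbitrary units.  A population — the unit on which expression
statistics are computed — is one ``(strain_id, condition_id, replicate_id)``
triple, and belongs to exactly one batch.

CSV is the canonical loss-free interchange format.  FCS 3.0 list-mode files
(float32, linear values) are supported for compatibility with cytometry
tooling; an FCS file holds one population, with the population keys stored as
custom TEXT keywords.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

KEY_COLUMNS = ["strain_id", "condition_id", "replicate_id", "batch_id"]
CHANNEL_COLUMNS = ["fsc", "ssc", "yfp_raw"]
EVENT_COLUMNS = KEY_COLUMNS + CHANNEL_COLUMNS

#: default instrument-channel-name -> canonical-column mapping used when
#: reading FCS files; instruments vary ("FSC-A" vs "FSC", FITC-like channel
#: names for YFP), so this is configurable everywhere it is used.
DEFAULT_CHANNEL_MAP: dict[str, str] = {
    "FSC": "fsc",
    "FSC-A": "fsc",
    "FSC-H": "fsc",
    "SSC": "ssc",
    "SSC-A": "ssc",
    "SSC-H": "ssc",
    "YFP": "yfp_raw",
    "FITC-A": "yfp_raw",
    "FITC": "yfp_raw",
}

# Acquisition thresholds applied by the instrument before recording (metadata;
# not re-applied to the data by default).
ACQUISITION_THRESHOLDS = {"fsc": 200.0, "ssc": 200.0}


class FormatError(ValueError):
    """A file does not conform to the expected event-table format."""


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Check that *events* has the canonical columns; return it unchanged.

    Raises :class:`FormatError` naming the first missing column.
    """
    for col in EVENT_COLUMNS:
        if col not in events.columns:
            raise FormatError(f"event table is missing required column {col!r}")
    return events


def sub_threshold_mask(events: pd.DataFrame) -> pd.Series:
    """Boolean mask of events violating the scatter-positivity invariant.

    Recorded events should have ``fsc > 0`` and ``ssc > 0`` (the instrument
    records only events above its scatter thresholds).  Reading never drops
    events; this flag lets callers audit files produced by other software.
    """
    return (events["fsc"] <= 0) | (events["ssc"] <= 0)


def population_keys(events: pd.DataFrame) -> pd.DataFrame:
    """Unique (strain, condition, replicate, batch) combinations present."""
    return events[KEY_COLUMNS].drop_duplicates().reset_index(drop=True)


def read_events(
    path: str | Path,
    format: str | None = None,
    channel_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read an event table from CSV or FCS.

    Parameters
    ----------
    path
        Input file.  When *format* is None it is inferred from the suffix.
    format
        ``"csv"`` or ``"fcs"``.
    channel_map
        Instrument-channel-name to canonical-column mapping for FCS input
        (defaults to :data:`DEFAULT_CHANNEL_MAP`).

    Returns
    -------
    pandas.DataFrame
        The canonical event table.  No events are dropped at read time.
    """
    path = Path(path)
    fmt = format or ("fcs" if path.suffix.lower() == ".fcs" else "csv")
    if fmt == "csv":
        df = pd.read_csv(path, dtype={c: str for c in KEY_COLUMNS})
        return validate_events(df)[EVENT_COLUMNS]
    if fmt == "fcs":
        return _read_fcs(path, channel_map or DEFAULT_CHANNEL_MAP)
    raise ValueError(f"unknown format {fmt!r}")


def write_events(
    events: pd.DataFrame,
    path: str | Path,
    format: str | None = None,
) -> Path:
    """Write an event table to CSV (loss-free) or FCS 3.0 (float32).

    FCS files hold a single population: all key columns must be constant.
    """
    if len(events) == 0:
        raise ValueError("refusing to write an empty event table")
    validate_events(events)
    path = Path(path)
    fmt = format or ("fcs" if path.suffix.lower() == ".fcs" else "csv")
    if fmt == "csv":
        events[EVENT_COLUMNS].to_csv(path, index=False)
        return path
    if fmt == "fcs":
        _write_fcs(events, path)
        return path
    raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Minimal FCS 3.0 support: list mode, $DATATYPE F (float32), linear values.
# One data set per file; population keys in custom TEXT keywords.
# ---------------------------------------------------------------------------

_FCS_KEY_KEYWORDS = {
    "strain_id": "NPSTRAIN",
    "condition_id": "NPCONDITION",
    "replicate_id": "NPREPLICATE",
    "batch_id": "NPBATCH",
}
_FCS_CHANNEL_NAMES = {"fsc": "FSC", "ssc": "SSC", "yfp_raw": "YFP"}
_DELIM = "/"


def _write_fcs(events: pd.DataFrame, path: Path) -> None:
    keys = events[KEY_COLUMNS].drop_duplicates()
    if len(keys) != 1:
        raise ValueError(
            "an FCS file holds one population; the table has "
            f"{len(keys)} distinct key combinations"
        )
    data = np.ascontiguousarray(
        events[CHANNEL_COLUMNS].to_numpy(dtype=np.float32)
    )
    n_events, n_par = data.shape
    data_bytes = data.tobytes()

    kw: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        # placeholders, fixed width so TEXT length is offset-independent
        "$BEGINDATA": "%012d" % 0,
        "$ENDDATA": "%012d" % 0,
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
    }
    for i, col in enumerate(CHANNEL_COLUMNS, start=1):
        kw[f"$P{i}N"] = _FCS_CHANNEL_NAMES[col]
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = str(int(np.ceil(float(data[:, i - 1].max()) + 1)))
    row = keys.iloc[0]
    for col, keyword in _FCS_KEY_KEYWORDS.items():
        kw[keyword] = str(row[col])

    def render(d: dict[str, str]) -> bytes:
        parts = [_DELIM]
        for k, v in d.items():
            if _DELIM in k or _DELIM in str(v):
                raise ValueError(f"FCS delimiter {_DELIM!r} in keyword {k!r}")
            parts.append(f"{k}{_DELIM}{v}{_DELIM}")
        return "".join(parts).encode("ascii")

    header_len = 58  # "FCS3.0" + 4 spaces + 6 x 8-byte offsets
    text = render(kw)
    text_start = header_len
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + len(data_bytes) - 1
    kw["$BEGINDATA"] = "%012d" % data_start
    kw["$ENDDATA"] = "%012d" % data_end
    text = render(kw)
    assert text_end == text_start + len(text) - 1

    def off(x: int) -> bytes:
        s = str(x)
        if len(s) > 8:
            s = "0"  # too large for the header; TEXT keywords carry it
        return s.rjust(8).encode("ascii")

    header = b"FCS3.0    " + b"".join(
        off(x)
        for x in (
            text_start,
            text_end,
            data_start if data_end <= 99999999 else 0,
            data_end if data_end <= 99999999 else 0,
            0,
            0,
        )
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data_bytes)


def _read_fcs(path: Path, channel_map: Mapping[str, str]) -> pd.DataFrame:
    raw = Path(path).read_bytes()
    if raw[:6] != b"FCS3.0" and raw[:6] != b"FCS3.1":
        raise FormatError(f"{path} is not an FCS 3.0/3.1 file")
    text_start = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_start : text_end + 1].decode("ascii", errors="replace")
    delim = text[0]
    fields = text[1:].split(delim)
    kw = {
        fields[i].strip(): fields[i + 1]
        for i in range(0, len(fields) - 1, 2)
        if fields[i].strip()
    }
    if kw.get("$DATATYPE") != "F" or kw.get("$MODE") != "L":
        raise FormatError("only list-mode float32 FCS data are supported")
    data_start = int(kw.get("$BEGINDATA") or raw[26:34])
    data_end = int(kw.get("$ENDDATA") or raw[34:42])
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    buf = raw[data_start : data_end + 1]
    data = np.frombuffer(buf, dtype=f"{endian}f4", count=n_tot * n_par)
    data = data.reshape(n_tot, n_par)

    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    columns: dict[str, np.ndarray] = {}
    for j, name in enumerate(names):
        canon = channel_map.get(name)
        if canon is not None:
            columns[canon] = data[:, j].astype(np.float64)
    for col in CHANNEL_COLUMNS:
        if col not in columns:
            raise FormatError(
                f"FCS file lacks a channel mapping to {col!r} "
                f"(channels present: {names})"
            )
    df = pd.DataFrame(columns)
    for col, keyword in _FCS_KEY_KEYWORDS.items():
        df[col] = kw.get(keyword, "")
    return df[EVENT_COLUMNS]
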