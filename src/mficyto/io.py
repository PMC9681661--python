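"""File I/O: a minimal FCS 3.1 reader/writer and the delimited-text dialect.

The delimited dialect is one CSV per sample (header = channel names, one row
per event, optionally gzip-compressed) with an optional ``<stem>.labels.csv``
sidecar holding per-event ground-truth or annotation columns, plus a single
sample-metadata CSV for the study.

The FCS support is deliberately small: single-dataset FCS 3.0/3.1 files with
list-mode float32 data, which is what this package writes and what modern
cytometry pipelines emit after preprocessing. ``$PnS`` (stain) names are
preferred over ``$PnN`` when present.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .events import ConfigurationError, EventTable, MficytoError

__all__ = [
    "write_fcs",
    "read_fcs",
    "write_delimited",
    "read_delimited",
    "read_events",
]

_DELIM = "/"


class FCSFormatError(MficytoError):
    pass


def write_fcs(path: str | Path, data: pd.DataFrame) -> None:
    """Write an events × channels frame as a single-dataset FCS 3.1 file.

    Data are stored as little-endian float32 list mode ($DATATYPE/F, $MODE/L).
    """
    path = Path(path)
    values = np.ascontiguousarray(data.to_numpy(dtype="<f4"))
    n_events, n_par = values.shape

    def build_text(begin_data: int, end_data: int) -> bytes:
        kv = {
            "$BEGINANALYSIS": "0",
            "$ENDANALYSIS": "0",
            "$BEGINSTEXT": "0",
            "$ENDSTEXT": "0",
            "$BEGINDATA": str(begin_data),
            "$ENDDATA": str(end_data),
            "$BYTEORD": "1,2,3,4",
            "$DATATYPE": "F",
            "$MODE": "L",
            "$NEXTDATA": "0",
            "$PAR": str(n_par),
            "$TOT": str(n_events),
        }
        for i, name in enumerate(data.columns, start=1):
            kv[f"$P{i}N"] = str(name).replace(_DELIM, "_")
            kv[f"$P{i}B"] = "32"
            kv[f"$P{i}E"] = "0,0"
            kv[f"$P{i}R"] = str(int(max(1.0, float(np.nanmax(values[:, i - 1])) + 1)))
        body = _DELIM + _DELIM.join(f"{k}{_DELIM}{v}" for k, v in kv.items()) + _DELIM
        return body.encode("ascii")

    # offsets depend on the text length; iterate to a fixed point
    text_start = 58
    begin_data = end_data = 0
    for _ in range(3):
        text = build_text(begin_data, end_data)
        new_begin = text_start + len(text)
        new_end = new_begin + values.nbytes - 1
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    text = build_text(begin_data, end_data)
    text_end = text_start + len(text) - 1

    def off(x: int) -> bytes:
        return (f"{x:>8d}" if x <= 99_999_999 else f"{0:>8d}").encode("ascii")

    header = b"FCS3.1    " + off(text_start) + off(text_end)
    header += off(begin_data if end_data <= 99_999_999 else 0)
    header += off(end_data if end_data <= 99_999_999 else 0)
    header += off(0) + off(0)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(values.tobytes())


def read_fcs(path: str | Path) -> pd.DataFrame:
    """Read a single-dataset FCS 3.0/3.1 file into an events × channels frame."""
    raw = Path(path).read_bytes()
    if not raw[:3] == b"FCS":
        raise FCSFormatError(f"{path} is not an FCS file")
    text_start = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_start : text_end + 1].decode("ascii", errors="replace")
    delim = text[0]
    parts = text.strip(delim).split(delim)
    kv = {parts[i].strip(): parts[i + 1] for i in range(0, len(parts) - 1, 2)}

    begin_data = int(kv["$BEGINDATA"])
    end_data = int(kv["$ENDDATA"])
    if begin_data == 0:
        begin_data, end_data = int(raw[26:34]), int(raw[34:42])
    n_par = int(kv["$PAR"])
    n_tot = int(kv["$TOT"])
    dtype = kv.get("$DATATYPE", "F").strip().upper()
    if dtype != "F":
        raise FCSFormatError(f"unsupported $DATATYPE {dtype!r} (only float supported)")
    byteord = kv.get("$BYTEORD", "1,2,3,4").strip()
    endian = "<" if byteord.startswith("1") else ">"
    names = []
    for i in range(1, n_par + 1):
        stain = kv.get(f"$P{i}S", "").strip()
        names.append(stain if stain else kv.get(f"$P{i}N", f"P{i}").strip())
        bits = int(kv.get(f"$P{i}B", "32"))
        if bits != 32:
            raise FCSFormatError("only 32-bit float parameters supported")
    buf = raw[begin_data : end_data + 1]
    expected = n_par * n_tot * 4
    if len(buf) < expected:
        raise FCSFormatError("truncated DATA segment")
    values = np.frombuffer(buf[:expected], dtype=f"{endian}f4").reshape(n_tot, n_par)
    return pd.DataFrame(values.astype(np.float64), columns=names)


def write_delimited(path: str | Path, table: EventTable, labels: pd.DataFrame | None = None) -> None:
    """Write events as CSV plus a provenance/labels sidecar.

    ``<path>`` holds the intensity matrix; ``<stem>.labels.csv[.gz]`` holds the
    per-event provenance (and any extra label columns passed in ``labels``).
    """
    path = Path(path)
    table.data.to_csv(path, index=False)
    side = table.meta.copy()
    if labels is not None:
        for col in labels.columns:
            side[col] = labels[col].to_numpy()
    side.to_csv(_sidecar_path(path), index=False)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".csv.gz", ".tsv.gz", ".csv", ".tsv", ".txt"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".labels.csv")
    return path.with_name(name + ".labels.csv")


def read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if ".tsv" in path.name or path.suffix == ".txt" else ","
    return pd.read_csv(path, sep=sep)


def _struct_is_fcs(path: Path) -> bool:
    if path.suffix.lower() == ".fcs":
        return True
    try:
        with open(path, "rb") as fh:
            return fh.read(3) == b"FCS"
    except (OSError, struct.error):
        return False


def read_events(
    paths: list[str | Path],
    metadata: pd.DataFrame,
    rename_map: dict[str, str] | None = None,
    panel: list[str] | None = None,
) -> EventTable:
    """Read per-sample event files and concatenate them with provenance.

    Each file corresponds to one row of ``metadata`` (matched by a ``path``
    column when present, else by file stem against ``sample_id``). Channels are
    aligned by name; a name mismatch across files without a ``rename_map``
    entry is an error. Channels absent from ``panel`` (when given) are
    preserved but flagged in ``EventTable.extra_channels``.
    """
    from .events import PROVENANCE_COLUMNS, validate_sample_metadata

    metadata = validate_sample_metadata(metadata)
    by_path = None
    if "path" in metadata.columns:
        by_path = {Path(p).name: i for i, p in metadata["path"].items()}

    frames, metas = [], []
    reference_cols: list[str] | None = None
    for p in paths:
        p = Path(p)
        df = read_fcs(p) if _struct_is_fcs(p) else read_delimited(p)
        if rename_map:
            df = df.rename(columns=rename_map)
        if reference_cols is None:
            reference_cols = list(df.columns)
        elif set(df.columns) != set(reference_cols):
            raise ConfigurationError(
                f"channel-name mismatch in {p.name}: "
                f"{sorted(set(df.columns) ^ set(reference_cols))} (supply rename_map)"
            )
        df = df[reference_cols]

        if by_path is not None and p.name in by_path:
            row = metadata.loc[by_path[p.name]]
        else:
            stem = p.name.split(".")[0]
            match = metadata[metadata["sample_id"].astype(str) == stem]
            if len(match) != 1:
                raise ConfigurationError(f"no metadata row for file {p.name}")
            row = match.iloc[0]
        meta = pd.DataFrame({c: [row[c]] * len(df) for c in PROVENANCE_COLUMNS})
        frames.append(df)
        metas.append(meta)

    data = pd.concat(frames, ignore_index=True)
    meta = pd.concat(metas, ignore_index=True)
    extra = tuple(c for c in data.columns if panel is not None and c not in panel)
    return EventTable(data, meta, transformed=False, extra_channels=extra)
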