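"""On-disk containers: JSON header + little-endian float32 payload + TSV events.

A container is a file triplet sharing a stem:

* ``<stem>.json`` — header: format_version, kind ("raw" | "epochs"),
  sfreq_hz, channel_labels, channel_positions, shape, dtype ("float32-le"),
  units ("uV"), participant_id; epochs additionally carry alignment and
  times_ms.
* ``<stem>.f32`` — payload, C-order (channel-major for raw; trials x
  channels x time for epochs), little-endian float32.
* ``<stem>.events.tsv`` — tab-separated event/metadata table, one row per
  trial plus a header row.

The layout is deliberately tool-agnostic so any environment can parse it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EVENT_COLUMNS, EpochSet, RawSession
from .errors import ContainerFormatError

FORMAT_VERSION = "1.0"

_RAW_FIELDS = [
    "format_version", "kind", "sfreq_hz", "channel_labels",
    "channel_positions", "shape", "dtype", "units", "participant_id",
]
_EPOCH_FIELDS = _RAW_FIELDS + ["alignment", "times_ms"]


def _paths(stem: str | Path) -> tuple[Path, Path, Path]:
    stem = Path(stem)
    return (
        stem.with_suffix(".json"),
        stem.with_suffix(".f32"),
        stem.with_suffix(".events.tsv"),
    )


def _write_events(events: pd.DataFrame, path: Path) -> None:
    events.to_csv(path, sep="\t", index=False)


def _read_events(path: Path) -> pd.DataFrame:
    ev = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in ev.columns]
    if missing:
        raise ContainerFormatError(f"events table missing columns: {missing}")
    return ev


def _read_header(path: Path, required: list[str]) -> dict:
    try:
        header = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ContainerFormatError(f"unparseable header {path}: {exc}") from exc
    for fieldname in required:
        if fieldname not in header:
            raise ContainerFormatError(
                f"header {path} missing required field {fieldname!r}"
            )
    if header["dtype"] != "float32-le":
        raise ContainerFormatError(
            f"header field 'dtype' must be 'float32-le', got {header['dtype']!r}"
        )
    return header


def _read_payload(path: Path, shape: tuple[int, ...]) -> np.ndarray:
    raw = path.read_bytes()
    expected = int(np.prod(shape)) * 4
    if len(raw) != expected:
        raise ContainerFormatError(
            f"payload {path} has {len(raw)} bytes, expected {expected} "
            f"for shape {tuple(shape)}"
        )
    return np.frombuffer(raw, dtype="<f4").reshape(shape).astype(float)


def write_raw(session: RawSession, stem: str | Path) -> list[Path]:
    """Write a RawSession as header + payload + events; returns the paths."""
    hpath, ppath, epath = _paths(stem)
    header = {
        "format_version": FORMAT_VERSION,
        "kind": "raw",
        "sfreq_hz": session.sfreq_hz,
        "channel_labels": list(session.channel_labels),
        "channel_positions": np.asarray(session.channel_positions).tolist(),
        "shape": list(session.data.shape),
        "dtype": "float32-le",
        "units": "uV",
        "participant_id": session.participant_id,
    }
    hpath.write_text(json.dumps(header, indent=1))
    ppath.write_bytes(np.ascontiguousarray(session.data, dtype="<f4").tobytes())
    _write_events(session.events, epath)
    return [hpath, ppath, epath]


def read_raw(stem: str | Path) -> RawSession:
    hpath, ppath, epath = _paths(stem)
    header = _read_header(hpath, _RAW_FIELDS)
    if header["kind"] != "raw":
        raise ContainerFormatError(
            f"expected kind 'raw', found {header['kind']!r} in {hpath}"
        )
    data = _read_payload(ppath, tuple(header["shape"]))
    return RawSession(
        data=data,
        sfreq_hz=float(header["sfreq_hz"]),
        channel_labels=list(header["channel_labels"]),
        channel_positions=np.asarray(header["channel_positions"], dtype=float),
        events=_read_events(epath),
        participant_id=str(header["participant_id"]),
    )


def write_epochs(epochs: EpochSet, stem: str | Path) -> list[Path]:
    hpath, ppath, epath = _paths(stem)
    header = {
        "format_version": FORMAT_VERSION,
        "kind": "epochs",
        "sfreq_hz": epochs.sfreq_hz,
        "channel_labels": list(epochs.channel_labels),
        "channel_positions": np.asarray(epochs.channel_positions).tolist(),
        "shape": list(epochs.data.shape),
        "dtype": "float32-le",
        "units": "uV",
        "participant_id": epochs.participant_id,
        "alignment": epochs.alignment,
        "times_ms": np.asarray(epochs.times_ms).tolist(),
    }
    hpath.write_text(json.dumps(header, indent=1))
    ppath.write_bytes(np.ascontiguousarray(epochs.data, dtype="<f4").tobytes())
    _write_events(epochs.metadata, epath)
    return [hpath, ppath, epath]


def read_epochs(stem: str | Path) -> EpochSet:
    hpath, ppath, epath = _paths(stem)
    header = _read_header(hpath, _EPOCH_FIELDS)
    if header["kind"] != "epochs":
        raise ContainerFormatError(
            f"expected kind 'epochs', found {header['kind']!r} in {hpath}"
        )
    data = _read_payload(ppath, tuple(header["shape"]))
    return EpochSet(
        data=data,
        sfreq_hz=float(header["sfreq_hz"]),
        channel_labels=list(header["channel_labels"]),
        channel_positions=np.asarray(header["channel_positions"], dtype=float),
        times_ms=np.asarray(header["times_ms"], dtype=float),
        alignment=str(header["alignment"]),
        metadata=_read_events(epath),
        participant_id=str(header["participant_id"]),
    )


def export_matrix(
    matrix,
    path: str | Path,
    row_labels=None,
    col_labels=None,
    index_name: str = "row",
) -> Path:
    """Export a labeled 2-D matrix (or DataFrame) as TSV; NaN rendered as NA."""
    path = Path(path)
    if isinstance(matrix, pd.DataFrame):
        df = matrix
    else:
        matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
        if matrix.size == 0:
            matrix = matrix.reshape(0, 0 if col_labels is None else len(col_labels))
        df = pd.DataFrame(matrix, index=row_labels, columns=col_labels)
        df.index.name = index_name
    df.to_csv(path, sep="\t", na_rep="NA")
    return path
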