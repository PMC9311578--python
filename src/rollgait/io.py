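"""Reading and writing roll traces and cohort manifests.

Three plain-text dialects are supported:

* the inertial-sensor manager export — whitespace/tab-delimited ``.txt`` with
  a header row naming the orientation columns (``Roll``, ``Pitch``, ``Yaw``,
  usually preceded by a sample ``Counter``) and optional ``//`` metadata lines
  before the header;
* simple two-column trace CSVs (``sample_index, roll_deg``);
* cohort manifest CSVs (``dog_id, trial_id, label, file``) tying trial files
  to subjects and diagnosis labels.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataIntegrityError, FormatError
from .traces import DogRecord, RollTrace

__all__ = [
    "read_sensor_export",
    "read_trace_csv",
    "write_trace_csv",
    "read_manifest",
    "write_manifest",
]

TRACE_COLUMNS = ("sample_index", "roll_deg")
MANIFEST_COLUMNS = ("dog_id", "trial_id", "label", "file")


def read_sensor_export(
    path: str | os.PathLike,
    column_name: str = "Roll",
    *,
    sampling_rate: float = 100.0,
    dog_id: str = "",
    trial_id: str = "",
) -> RollTrace:
    """Parse one orientation column from a sensor-manager ``.txt`` export.

    Leading ``//`` comment lines are skipped; the first non-comment,
    non-blank line is the header. Extra columns (counters, timestamps,
    pitch/yaw) are ignored. Sample order in the file is preserved.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    header: list[str] | None = None
    rows: list[float] = []
    col = -1
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("//"):
            continue
        fields = line.split()
        if header is None:
            header = fields
            if column_name not in header:
                raise FormatError(
                    f"{path}: column {column_name!r} not found; "
                    f"available columns: {', '.join(header)}"
                )
            col = header.index(column_name)
            continue
        if len(fields) <= col:
            raise FormatError(f"{path}, line {lineno}: row has too few columns")
        try:
            rows.append(float(fields[col]))
        except ValueError:
            raise FormatError(
                f"{path}, line {lineno}: non-numeric value {fields[col]!r} "
                f"in column {column_name!r}"
            ) from None
    if header is None:
        raise FormatError(f"{path}: no header row found")
    if not rows:
        raise FormatError(f"{path}: no data rows after the header")
    return RollTrace(
        np.asarray(rows), sampling_rate, dog_id=dog_id, trial_id=trial_id
    )


def read_trace_csv(
    path: str | os.PathLike,
    *,
    sampling_rate: float = 100.0,
    dog_id: str = "",
    trial_id: str = "",
) -> RollTrace:
    """Read a two-column trace CSV (``sample_index, roll_deg``)."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as exc:
        raise FormatError(f"{path}: not a readable trace CSV ({exc})") from exc
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing column(s) {missing}; found {list(df.columns)}"
        )
    if len(df) == 0:
        raise FormatError(f"{path}: trace CSV contains no samples")
    values = pd.to_numeric(df["roll_deg"], errors="coerce").to_numpy(dtype=np.float64)
    if np.any(~np.isfinite(values)):
        bad = int(np.flatnonzero(~np.isfinite(values))[0])
        raise FormatError(f"{path}: non-numeric roll_deg value at data row {bad}")
    return RollTrace(values, sampling_rate, dog_id=dog_id, trial_id=trial_id)


def write_trace_csv(trace: RollTrace, path: str | os.PathLike) -> None:
    """Write a trace as CSV with full float precision (exact round trip)."""
    df = pd.DataFrame(
        {"sample_index": np.arange(len(trace)), "roll_deg": trace.values}
    )
    df.to_csv(path, index=False)


def write_manifest(
    cohort: list[DogRecord],
    out_dir: str | os.PathLike,
    *,
    manifest_name: str = "manifest.csv",
) -> Path:
    """Write one CSV per trial plus a manifest CSV; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        for trace in rec.traces:
            fname = f"{rec.dog_id}_{trace.trial_id}.csv"
            write_trace_csv(trace, out / fname)
            rows.append(
                {
                    "dog_id": rec.dog_id,
                    "trial_id": trace.trial_id,
                    "label": rec.label,
                    "file": fname,
                }
            )
    manifest = out / manifest_name
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest, index=False)
    return manifest


def read_manifest(path: str | os.PathLike) -> list[DogRecord]:
    """Load a cohort manifest; trial files are resolved relative to it.

    Dogs appear in first-occurrence order; a dog listed with two different
    labels is a data-integrity error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"{path}: not a readable manifest CSV ({exc})") from exc
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: manifest missing column(s) {missing}; found {list(df.columns)}"
        )
    if len(df) == 0:
        return []

    records: dict[str, DogRecord] = {}
    for _, row in df.iterrows():
        dog_id = str(row["dog_id"])
        label = int(row["label"])
        if label not in (0, 1):
            raise DataIntegrityError(f"{path}: dog {dog_id!r} has label {label}")
        trace = read_trace_csv(
            path.parent / str(row["file"]),
            dog_id=dog_id,
            trial_id=str(row["trial_id"]),
        )
        if dog_id not in records:
            records[dog_id] = DogRecord(dog_id=dog_id, label=label, traces=[])
        elif records[dog_id].label != label:
            raise DataIntegrityError(
                f"{path}: dog {dog_id!r} listed with conflicting labels "
                f"{records[dog_id].label} and {label}"
            )
        records[dog_id].traces.append(trace)
    return list(records.values())
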