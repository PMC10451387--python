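"""Trial, report and table file I/O.

File dialect (fixed for the whole package): comma-separated values, ``.``
decimal separator, UTF-8, one header row with exact column names. Trial
files carry ``time_s, cop_x_cm, cop_y_cm`` plus optional ``# key: value``
comment lines before the header holding the condition label, subject id and
sampling rate, so that a write/read round trip preserves the full trial.
"""
from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyTrialError, FormatError, SamplingError
from .types import (
    FEATURE_NAMES,
    Condition,
    CopTrial,
    SessionReport,
    SwayFeatures,
)

TRIAL_COLUMNS = ("time_s", "cop_x_cm", "cop_y_cm")
SCHEMA_VERSION = 1

#: Relative tolerance on timestamp jitter when inferring the sampling rate.
FS_INFER_REL_TOL = 0.01


def _read_metadata(path: Path) -> tuple[dict[str, str], int]:
    """Parse leading ``# key: value`` comment lines; return metadata and count."""
    meta: dict[str, str] = {}
    n_comments = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comments += 1
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta, n_comments


def read_cop_trial(
    path: str | Path,
    condition: Condition | str | None = None,
    fs: float | None = None,
) -> CopTrial:
    """Read a CoP trial from a delimited text file.

    The file must contain the columns ``time_s, cop_x_cm, cop_y_cm``.
    The sampling rate is inferred from the median timestamp step unless
    ``fs`` is given; timestamps are then snapped to the uniform grid
    ``t0 + k/fs`` (raw jitter beyond 1% of one step is rejected).

    Parameters
    ----------
    condition : optional
        Overrides the condition stored in the file's metadata.
    fs : optional
        Overrides the inferred sampling rate, in Hz.
    """
    path = Path(path)
    meta, n_comments = _read_metadata(path)
    try:
        df = pd.read_csv(path, skiprows=n_comments)
    except Exception as exc:  # noqa: BLE001 - surfaced as format error
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path} is missing required column(s): {missing}")
    if len(df) < 2:
        raise EmptyTrialError(f"{path} has {len(df)} data rows; need at least 2")

    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise SamplingError(f"{path}: timestamps are not strictly increasing")
    step = float(np.median(dt))
    if np.any(np.abs(dt - step) > FS_INFER_REL_TOL * step):
        raise SamplingError(
            f"{path}: timestamps non-uniform beyond {FS_INFER_REL_TOL:.0%} of one step"
        )
    if fs is None:
        fs_meta = meta.get("fs_hz")
        fs = float(fs_meta) if fs_meta is not None else 1.0 / step
    t_uniform = t[0] + np.arange(len(t)) / fs

    if condition is None:
        cond_label = meta.get("condition")
        if cond_label is None:
            raise FormatError(
                f"{path} has no condition metadata and none was supplied"
            )
        condition = Condition(cond_label)
    elif isinstance(condition, str):
        condition = Condition(condition)

    return CopTrial(
        time=t_uniform,
        x=df["cop_x_cm"].to_numpy(dtype=float),
        y=df["cop_y_cm"].to_numpy(dtype=float),
        fs=float(fs),
        condition=condition,
        subject_id=meta.get("subject_id", ""),
    )


def write_cop_trial(trial: CopTrial, path: str | Path) -> None:
    """Write a trial to a delimited text file readable by :func:`read_cop_trial`.

    Values are written with enough digits that a round trip loses less than
    1e-9 cm per sample.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# condition: {trial.condition.value}\n")
        if trial.subject_id:
            fh.write(f"# subject_id: {trial.subject_id}\n")
        fh.write(f"# fs_hz: {trial.fs!r}\n")
        fh.write(",".join(TRIAL_COLUMNS) + "\n")
        for t, x, y in zip(trial.time, trial.x, trial.y):
            fh.write(f"{t:.10f},{x:.10f},{y:.10f}\n")


def write_session_report(report: SessionReport, path: str | Path) -> None:
    """Serialize a session report to JSON.

    The document carries a ``schema_version`` field, the per-condition SI
    values with their feature vectors, and the overall (mean) SI.
    """
    doc = {
        "schema_version": SCHEMA_VERSION,
        "subject_id": report.subject_id,
        "conditions": [
            {
                "condition": cond.value,
                "si": float(si),
                "features": (
                    report.feature_table[cond].to_dict()
                    if cond in report.feature_table
                    else None
                ),
            }
            for cond, si in report.per_condition_si.items()
        ],
        "missing_conditions": [c.value for c in report.missing_conditions],
        "overall_si": float(report.overall_si),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_session_report(path: str | Path) -> SessionReport:
    """Load a session report written by :func:`write_session_report`."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    per_condition = {}
    features = {}
    for entry in doc["conditions"]:
        cond = Condition(entry["condition"])
        per_condition[cond] = float(entry["si"])
        if entry.get("features") is not None:
            features[cond] = SwayFeatures.from_dict(entry["features"])
    return SessionReport(
        subject_id=doc.get("subject_id", ""),
        per_condition_si=per_condition,
        feature_table=features,
        missing_conditions=[Condition(c) for c in doc.get("missing_conditions", [])],
        overall_si=float(doc["overall_si"]),
    )


# ---------------------------------------------------------------------------
# feature / training tables

TABLE_KEY_COLUMNS = ("subject_id", "condition")


def write_feature_table(
    rows: list[tuple[str, Condition, SwayFeatures]], path: str | Path
) -> None:
    """Write one row per (subject, condition) with the ten feature columns."""
    records = [
        {"subject_id": sid, "condition": cond.value, **feats.to_dict()}
        for sid, cond, feats in rows
    ]
    pd.DataFrame.from_records(
        records, columns=list(TABLE_KEY_COLUMNS) + list(FEATURE_NAMES)
    ).to_csv(path, index=False)


def read_feature_table(path: str | Path) -> list[tuple[str, Condition, SwayFeatures]]:
    df = pd.read_csv(path)
    missing = [c for c in TABLE_KEY_COLUMNS + FEATURE_NAMES if c not in df.columns]
    if missing:
        raise FormatError(f"{path} is missing column(s): {missing}")
    return [
        (
            str(row["subject_id"]),
            Condition(row["condition"]),
            SwayFeatures.from_dict({n: row[n] for n in FEATURE_NAMES}),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# raw device signals


def read_pressure_frames(path: str | Path, geometry=None):
    """Read a pressure-grid recording from long-format delimited text.

    Expected columns: ``time_s, row, col, force_kgf``; cells not listed in a
    frame are zero. Returns a :class:`~ictsib.cop.PressureFrameSeries`.
    """
    from .cop import GridGeometry, PressureFrameSeries

    geometry = geometry or GridGeometry()
    df = pd.read_csv(path)
    required = ("time_s", "row", "col", "force_kgf")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path} is missing column(s): {missing}")
    times = np.sort(df["time_s"].unique())
    index = {t: i for i, t in enumerate(times)}
    frames = np.zeros((len(times), geometry.n_rows, geometry.n_cols))
    rows = df["row"].to_numpy(dtype=int)
    cols = df["col"].to_numpy(dtype=int)
    if rows.min() < 0 or rows.max() >= geometry.n_rows or cols.min() < 0 or cols.max() >= geometry.n_cols:
        raise FormatError(f"{path}: row/col indices outside the {geometry.n_rows}x{geometry.n_cols} grid")
    t_idx = np.array([index[t] for t in df["time_s"]])
    np.add.at(frames, (t_idx, rows, cols), df["force_kgf"].to_numpy(dtype=float))
    return PressureFrameSeries(geometry=geometry, frames=frames, time=times)


def write_pressure_frames(series, path: str | Path) -> None:
    """Write a pressure-grid recording as long-format text (nonzero cells only)."""
    t_idx, rows, cols = np.nonzero(series.frames)
    pd.DataFrame(
        {
            "time_s": series.time[t_idx],
            "row": rows,
            "col": cols,
            "force_kgf": series.frames[t_idx, rows, cols],
        }
    ).to_csv(path, index=False, float_format="%.6f")


def read_corner_loads(
    path: str | Path, board_length_cm: float = 43.3, board_width_cm: float = 22.8
):
    """Read four-corner load-cell signals from delimited text.

    Expected columns: ``time_s, tl_kgf, tr_kgf, bl_kgf, br_kgf``.
    """
    from .cop import CornerLoadSeries

    df = pd.read_csv(path)
    required = ("time_s", "tl_kgf", "tr_kgf", "bl_kgf", "br_kgf")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path} is missing column(s): {missing}")
    return CornerLoadSeries(
        tl=df["tl_kgf"].to_numpy(dtype=float),
        tr=df["tr_kgf"].to_numpy(dtype=float),
        bl=df["bl_kgf"].to_numpy(dtype=float),
        br=df["br_kgf"].to_numpy(dtype=float),
        board_length_cm=board_length_cm,
        board_width_cm=board_width_cm,
        time=df["time_s"].to_numpy(dtype=float),
    )


def write_corner_loads(loads, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": loads.time,
            "tl_kgf": loads.tl,
            "tr_kgf": loads.tr,
            "bl_kgf": loads.bl,
            "br_kgf": loads.br,
        }
    ).to_csv(path, index=False, float_format="%.8f")
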