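"""Cohort, annotation and chart-table I/O.

All interchange files are UTF-8 CSV with a header row.  Times are integer
minutes since the end of the operation (0-based; intervals are half-open).
Patient trace tables are long format with one row per
(patient_id, signal, minute); raw (pre-gridding) stream tables use a float
``time`` column instead of ``minute``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, DataError, FormatError

#: Canonical monitored signals: heart rate (bpm), invasive arterial blood
#: pressures (systolic / diastolic / mean, mmHg) and pulse oximetry (%).
SIGNALS = ("HR", "ABP_SYS", "ABP_DIA", "ABP_MEAN", "SPO2")

#: Default monitoring horizon: 7 postoperative days on a 1-minute grid.
DEFAULT_HORIZON = 7 * 24 * 60

#: Coarse clinical-note time frames mapped to fixed 6-hour blocks of the
#: calendar day (minutes from midnight of the given postoperative day).
FRAME_BLOCKS = {
    "night": (0, 360),
    "morning": (360, 720),
    "afternoon": (720, 1080),
    "evening": (1080, 1440),
}

ANNOTATION_KINDS = ("PN", "CEN")


@dataclass
class SignalTrace:
    """One signal's 1-minute gridded series for one patient.

    ``value`` is NaN wherever ``valid`` is False (missing, dropout, or
    before the first / after the last true measurement).
    """

    patient_id: str
    signal: str
    minutes: np.ndarray
    value: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.minutes = np.asarray(self.minutes, dtype=int)
        self.value = np.asarray(self.value, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.signal not in SIGNALS:
            raise DataError(f"unknown signal {self.signal!r}")
        if not (
            len(self.minutes) == len(self.value) == len(self.valid)
        ):
            raise ContractError("minutes/value/valid length mismatch")
        if len(self.minutes) and np.any(np.diff(self.minutes) != 1):
            raise ContractError("minute grid must be consecutive 1-minute steps")
        if np.any(~np.isfinite(self.value[self.valid])):
            raise DataError(
                f"non-finite values at valid minutes ({self.patient_id}/{self.signal})"
            )

    @property
    def invalid_fraction(self) -> float:
        return float(np.mean(~self.valid)) if len(self.valid) else 1.0


@dataclass
class PatientRecord:
    """All five canonical signal traces for one patient on a shared grid."""

    patient_id: str
    traces: dict
    horizon: int = DEFAULT_HORIZON
    excluded: bool = False
    invalid_fractions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [s for s in SIGNALS if s not in self.traces]
        if missing:
            raise DataError(
                f"patient {self.patient_id!r} is missing signal(s): {', '.join(missing)}"
            )
        lengths = {len(t.minutes) for t in self.traces.values()}
        if lengths != {self.horizon}:
            raise ContractError(
                f"patient {self.patient_id!r}: trace grids do not match horizon {self.horizon}"
            )
        if not self.invalid_fractions:
            self.invalid_fractions = {
                s: self.traces[s].invalid_fraction for s in SIGNALS
            }

    def flag_exclusion(self, threshold: float = 0.1) -> bool:
        """Flag the record excluded if any sensor is unusable for more than
        ``threshold`` of the monitoring time.  Flags, never deletes."""
        self.excluded = any(f > threshold for f in self.invalid_fractions.values())
        return self.excluded


@dataclass
class ClinicalAnnotation:
    """A timestamped (or coarsely framed) clinical note label."""

    patient_id: str
    kind: str  # "PN" (daily progress note) or "CEN" (clinical event note)
    label: str
    start: int  # minute
    end: int  # minute; == start for exact timestamps, exclusive otherwise

    def __post_init__(self) -> None:
        if self.kind not in ANNOTATION_KINDS:
            raise DataError(f"unknown annotation kind {self.kind!r}")
        if self.end < self.start:
            raise DataError("annotation interval end precedes start")


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s) {', '.join(missing)}")


def read_cohort(paths, horizon: int = DEFAULT_HORIZON,
                exclusion_threshold: float = 0.1):
    """Read long-format trace tables into one :class:`PatientRecord` per patient.

    Minutes outside ``[0, horizon)`` are dropped; minutes absent from the
    table (or with NaN values) are marked invalid.  Duplicate
    (patient, signal, minute) rows and unknown signal names are errors.
    Records breaching the sensor-dropout exclusion rule are flagged
    ``excluded`` but still returned.
    """
    if isinstance(paths, (str, bytes, os.PathLike)) or hasattr(paths, "read"):
        paths = [paths]
    frames = []
    for p in paths:
        df = pd.read_csv(p, float_precision="round_trip")
        _require_columns(df, ("patient_id", "signal", "minute", "value"), str(p))
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)

    unknown = set(table["signal"].unique()) - set(SIGNALS)
    if unknown:
        raise DataError(f"unknown signal name(s): {', '.join(sorted(map(str, unknown)))}")
    table = table[(table["minute"] >= 0) & (table["minute"] < horizon)]
    dup = table.duplicated(subset=("patient_id", "signal", "minute"))
    if dup.any():
        first = table[dup].iloc[0]
        raise DataError(
            "duplicate grid point: "
            f"({first['patient_id']}, {first['signal']}, {int(first['minute'])})"
        )

    records = []
    grid = np.arange(horizon)
    for pid, chunk in table.groupby("patient_id", sort=True):
        traces = {}
        present = set(chunk["signal"].unique())
        missing = [s for s in SIGNALS if s not in present]
        if missing:
            raise DataError(
                f"patient {pid!r} is missing signal(s): {', '.join(missing)}"
            )
        for sig, rows in chunk.groupby("signal"):
            value = np.full(horizon, np.nan)
            value[rows["minute"].to_numpy(dtype=int)] = rows["value"].to_numpy(dtype=float)
            valid = np.isfinite(value)
            value[~valid] = np.nan
            traces[sig] = SignalTrace(str(pid), sig, grid, value, valid)
        rec = PatientRecord(str(pid), traces, horizon)
        rec.flag_exclusion(exclusion_threshold)
        records.append(rec)
    return records


def write_cohort(records, path) -> None:
    """Write :class:`PatientRecord` traces as a long-format CSV (valid minutes only)."""
    parts = []
    for rec in records:
        for sig in SIGNALS:
            tr = rec.traces[sig]
            m = tr.minutes[tr.valid]
            parts.append(pd.DataFrame({
                "patient_id": rec.patient_id,
                "signal": sig,
                "minute": m,
                "value": tr.value[tr.valid],
            }))
    out = (pd.concat(parts, ignore_index=True) if parts
           else pd.DataFrame(columns=["patient_id", "signal", "minute", "value"]))
    out.to_csv(path, index=False)


def write_chart_table(charts, path) -> None:
    """Write control charts to CSV (minute, chart_name, statistic, limit, alarm).

    Round-trips losslessly through :func:`read_chart_table` (floats are
    written at full precision).
    """
    grids = {tuple(np.asarray(c.minutes)) for c in charts}
    if len(grids) > 1:
        raise ContractError("charts do not share a time grid")
    rows = []
    for c in charts:
        rows.append(pd.DataFrame({
            "minute": np.asarray(c.minutes, dtype=int),
            "chart_name": c.name,
            "statistic": c.statistic,
            "limit": c.limit,
            "alarm": c.alarm.astype(bool),
            "alpha": c.alpha,
        }))
    out = (pd.concat(rows, ignore_index=True) if rows
           else pd.DataFrame(columns=["minute", "chart_name", "statistic",
                                      "limit", "alarm", "alpha"]))
    out.to_csv(path, index=False)


def read_chart_table(path):
    """Inverse of :func:`write_chart_table`."""
    from .control_charts import ControlChart  # local import to avoid a cycle

    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ("minute", "chart_name", "statistic", "limit", "alarm"),
                     str(path))
    charts = []
    for name, rows in df.groupby("chart_name", sort=False):
        rows = rows.sort_values("minute")
        alpha = float(rows["alpha"].iloc[0]) if "alpha" in rows else float("nan")
        charts.append(ControlChart(
            name=str(name),
            minutes=rows["minute"].to_numpy(dtype=int),
            statistic=rows["statistic"].to_numpy(dtype=float),
            limit=rows["limit"].to_numpy(dtype=float),
            alarm=rows["alarm"].to_numpy(dtype=bool),
            alpha=alpha,
        ))
    return charts


def read_annotations(path, horizon: int = DEFAULT_HORIZON):
    """Read clinical-note annotations.

    Each row carries either an exact ``minute`` or a coarse ``(day, frame)``
    pair — exactly one of the two.  Coarse frames resolve to fixed 6-hour
    blocks of the given postoperative day.  Returned sorted by patient then
    time.
    """
    df = pd.read_csv(path)
    _require_columns(df, ("patient_id", "kind", "label"), str(path))
    has_minute = "minute" in df.columns
    has_frame = "day" in df.columns and "frame" in df.columns
    out = []
    for i, row in df.iterrows():
        minute = row.get("minute") if has_minute else None
        day = row.get("day") if has_frame else None
        frame = row.get("frame") if has_frame else None
        minute_given = minute is not None and not pd.isna(minute)
        frame_given = (day is not None and not pd.isna(day)
                       and isinstance(frame, str) and frame != "")
        if minute_given == frame_given:
            raise FormatError(
                f"annotation row {i}: exactly one of minute or (day, frame) required"
            )
        if minute_given:
            start = end = int(minute)
        else:
            if frame not in FRAME_BLOCKS:
                raise FormatError(f"annotation row {i}: unknown frame {frame!r}")
            lo, hi = FRAME_BLOCKS[frame]
            start, end = int(day) * 1440 + lo, int(day) * 1440 + hi
        if not (0 <= start < horizon):
            raise DataError(f"annotation row {i}: time outside the monitoring horizon")
        out.append(ClinicalAnnotation(str(row["patient_id"]), str(row["kind"]),
                                      str(row["label"]), start, min(end, horizon)))
    out.sort(key=lambda a: (a.patient_id, a.start, a.end))
    return out


def read_raw_streams(paths):
    """Read raw (irregularly sampled) stream tables.

    Expects columns patient_id, signal, time (float minutes), value.
    Returns ``{patient_id: {signal: RawStream}}``.
    """
    from .preprocess import RawStream  # local import to avoid a cycle

    if isinstance(paths, (str, bytes, os.PathLike)) or hasattr(paths, "read"):
        paths = [paths]
    frames = []
    for p in paths:
        df = pd.read_csv(p, float_precision="round_trip")
        _require_columns(df, ("patient_id", "signal", "time", "value"), str(p))
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    unknown = set(table["signal"].unique()) - set(SIGNALS)
    if unknown:
        raise DataError(f"unknown signal name(s): {', '.join(sorted(map(str, unknown)))}")
    out = {}
    for (pid, sig), rows in table.groupby(["patient_id", "signal"], sort=True):
        rows = rows.sort_values("time")
        out.setdefault(str(pid), {})[sig] = RawStream(
            str(pid), sig,
            rows["time"].to_numpy(dtype=float),
            rows["value"].to_numpy(dtype=float),
        )
    return out


def write_raw_streams(cohort, path) -> None:
    """Write ``{patient_id: {signal: RawStream}}`` as a raw-stream CSV."""
    parts = []
    for pid in sorted(cohort):
        for sig in SIGNALS:
            if sig not in cohort[pid]:
                continue
            st = cohort[pid][sig]
            parts.append(pd.DataFrame({
                "patient_id": pid, "signal": sig,
                "time": st.times, "value": st.values,
            }))
    out = (pd.concat(parts, ignore_index=True) if parts
           else pd.DataFrame(columns=["patient_id", "signal", "time", "value"]))
    out.to_csv(path, index=False)
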