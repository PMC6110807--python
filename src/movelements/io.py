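"""Reading, validating and writing marker-trajectory and result tables.

Trajectory input is a delimited text table (comma default, tab accepted) with
an optional ``time`` column and 1-3 position columns labelled ``x``
(medio-lateral), ``y`` (antero-posterior), ``z`` (vertical).  Internal units
are fixed at millimetres and seconds; declared input units are converted on
read.  Result tables (movement elements, fits, summaries) are written as CSV
with a single header row and round-trip losslessly through the matching
readers.
"""

from __future__ import annotations

import csv
import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

AXIS_NAMES = ("x", "y", "z")

_POSITION_FACTORS = {"mm": 1.0, "cm": 10.0, "m": 1000.0}
_TIME_FACTORS = {"s": 1.0, "ms": 1e-3}


class TrajectoryValidationError(ValueError):
    """Base class for trajectory-file validation failures."""


class MissingColumnError(TrajectoryValidationError):
    pass


class NonMonotonicTimeError(TrajectoryValidationError):
    pass


class NonUniformSamplingError(TrajectoryValidationError):
    pass


class TooFewSamplesError(TrajectoryValidationError):
    pass


@dataclass
class FormatConfig:
    """How to interpret a delimited trajectory table.

    ``delimiter=None`` sniffs between comma and tab.  If ``time_column`` is
    None and the file has no ``time`` column, ``sampling_rate_hz`` must be
    declared and a time vector starting at 0 is synthesised.
    """

    delimiter: Optional[str] = None
    time_column: Optional[str] = "time"
    position_units: str = "mm"
    time_units: str = "s"
    sampling_rate_hz: Optional[float] = None
    time_tolerance_s: float = 1e-6


@dataclass
class TrajectoryRecording:
    """Uniformly sampled multi-axis position time series.

    time is in seconds (strictly increasing, uniform step), positions in
    millimetres keyed by axis label, sampling_rate in Hz.  metadata is
    free-form (subject id, task name, marker name, provenance).
    """

    time: np.ndarray
    axes: dict[str, np.ndarray]
    sampling_rate: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    @property
    def axis_names(self) -> tuple[str, ...]:
        return tuple(self.axes.keys())

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def validate(self, time_tolerance_s: float = 1e-6) -> "TrajectoryRecording":
        if self.sampling_rate <= 0:
            raise TrajectoryValidationError(
                f"sampling_rate must be positive, got {self.sampling_rate}"
            )
        if self.time.size < 2:
            raise TooFewSamplesError(
                f"need at least 2 samples, got {self.time.size}"
            )
        if not (1 <= len(self.axes) <= 3):
            raise TrajectoryValidationError(
                f"need 1-3 position axes, got {sorted(self.axes)}"
            )
        for name, series in self.axes.items():
            if name not in AXIS_NAMES:
                raise TrajectoryValidationError(f"unknown axis label {name!r}")
            if series.size != self.time.size:
                raise TrajectoryValidationError(
                    f"axis {name!r} has {series.size} samples but time has "
                    f"{self.time.size}"
                )
        steps = np.diff(self.time)
        if np.any(steps <= 0):
            row = int(np.argmax(steps <= 0)) + 1
            raise NonMonotonicTimeError(
                f"time is not strictly increasing at row {row} "
                f"(t={self.time[row]!r})"
            )
        expected = 1.0 / self.sampling_rate
        dev = np.max(np.abs(steps - expected))
        if dev > time_tolerance_s:
            row = int(np.argmax(np.abs(steps - expected))) + 1
            raise NonUniformSamplingError(
                f"time step deviates from 1/sampling_rate by {dev:.3g} s "
                f"(> {time_tolerance_s:.3g} s) at row {row}"
            )
        return self


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    try:
        return csv.Sniffer().sniff(header, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def read_trajectory(path, config: Optional[FormatConfig] = None) -> TrajectoryRecording:
    """Read a delimited trajectory table into a validated recording.

    Raises a :class:`TrajectoryValidationError` subclass naming the offending
    column or row on malformed input.
    """
    config = config or FormatConfig()
    path = Path(path)
    delim = config.delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delim)
    df.columns = [c.strip().lower() for c in df.columns]

    axis_cols = [c for c in AXIS_NAMES if c in df.columns]
    if not axis_cols:
        raise MissingColumnError(
            f"no position columns among {AXIS_NAMES} in {path.name} "
            f"(found {list(df.columns)})"
        )
    if len(df) < 2:
        raise TooFewSamplesError(f"{path.name}: need at least 2 samples, got {len(df)}")

    pos_factor = _POSITION_FACTORS.get(config.position_units)
    if pos_factor is None:
        raise ValueError(f"unknown position units {config.position_units!r}")
    time_factor = _TIME_FACTORS.get(config.time_units)
    if time_factor is None:
        raise ValueError(f"unknown time units {config.time_units!r}")

    tcol = config.time_column
    if tcol is not None and tcol in df.columns:
        time = df[tcol].to_numpy(dtype=float) * time_factor
        steps = np.diff(time)
        if np.any(steps <= 0):
            row = int(np.argmax(steps <= 0)) + 1
            raise NonMonotonicTimeError(
                f"{path.name}: column {tcol!r} not strictly increasing at row {row}"
            )
        dt = float((time[-1] - time[0]) / (len(time) - 1))
        sampling_rate = 1.0 / dt
    elif config.sampling_rate_hz is not None:
        sampling_rate = float(config.sampling_rate_hz)
        time = np.arange(len(df)) / sampling_rate
    else:
        raise MissingColumnError(
            f"{path.name}: no {tcol!r} column and no declared sampling rate"
        )

    axes = {c: df[c].to_numpy(dtype=float) * pos_factor for c in axis_cols}
    rec = TrajectoryRecording(
        time=time,
        axes=axes,
        sampling_rate=sampling_rate,
        metadata={"source": str(path)},
    )
    return rec.validate(time_tolerance_s=config.time_tolerance_s)


def write_trajectory(recording: TrajectoryRecording, path, delimiter: str = ",") -> None:
    """Write a recording as a delimited table with a time column (s, mm)."""
    data = {"time": recording.time}
    data.update(recording.axes)
    pd.DataFrame(data).to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Result tables

ELEMENT_COLUMNS = [
    "axis",
    "t_start",
    "t_end",
    "t_f",
    "D",
    "mean_abs_velocity",
    "peak_abs_velocity",
    "sign",
    "boundary",
    "fit_r",
    "K",
    "kept",
    "reason",
]


def write_table(records: Sequence, path, columns: Optional[list[str]] = None) -> None:
    """Write a homogeneous list of result records as CSV.

    Each record must expose ``to_row()`` returning a flat dict, or be a
    dataclass whose scalar fields are taken directly.  An empty list produces
    a header-only file (movement-element columns unless ``columns`` given).
    """
    rows = []
    for rec in records:
        if hasattr(rec, "to_row"):
            rows.append(rec.to_row())
        elif dataclasses.is_dataclass(rec):
            rows.append(
                {
                    f.name: getattr(rec, f.name)
                    for f in dataclasses.fields(rec)
                    if np.isscalar(getattr(rec, f.name))
                    or getattr(rec, f.name) is None
                }
            )
        else:
            raise TypeError(f"cannot serialise record of type {type(rec).__name__}")
    if rows:
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame(columns=columns or ELEMENT_COLUMNS)
    df.to_csv(path, index=False)


def read_elements(path) -> list:
    """Read a movement-element CSV written by :func:`write_table`.

    Sample arrays are not stored in the table, so returned elements carry
    empty sample vectors; all scalar fields round-trip exactly.
    """
    from movelements.decompose import MovementElement

    df = pd.read_csv(path)
    elements = []
    for _, row in df.iterrows():
        fit_r = row.get("fit_r")
        K = row.get("K")
        elements.append(
            MovementElement(
                axis=str(row["axis"]),
                t_start=float(row["t_start"]),
                t_end=float(row["t_end"]),
                D=float(row["D"]),
                sign=int(row["sign"]),
                boundary_flag=bool(row["boundary"]),
                sample_times=np.array([]),
                sample_velocities=np.array([]),
                peak_abs_velocity=float(row["peak_abs_velocity"]),
                fit_r=None if fit_r is None or (isinstance(fit_r, float) and math.isnan(fit_r)) else float(fit_r),
                K=None if K is None or (isinstance(K, float) and math.isnan(K)) else float(K),
                kept=None if pd.isna(row.get("kept")) else bool(row["kept"]),
                reason=None if pd.isna(row.get("reason")) else str(row["reason"]),
            )
        )
    return elements
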