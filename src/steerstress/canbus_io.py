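"""I/O for decoded CAN-bus tables: steering angle, speed, and participant data.

Steering angle arrives as a signed series (clockwise positive) nominally
sampled at 100 Hz with 0.1 degree resolution and a +/-450 degree physical
range; speed nominally at 50 Hz in mph.  Files are plain UTF-8 CSV with a
header row (``time_s,angle_deg`` / ``time_s,speed_mph``); participant
self-report and physiology tables are long-format CSV
(``participant,metric,phase,value``).

Raw CAN logs frequently contain repeated timestamps (the decoder's clock
resolution coarser than the bus rate); :func:`clean_timestamps` keeps the
first sample at each time value.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import AngleRangeError, EmptyTraceError, FormatError

MAX_ANGLE_DEG = 450.0

#: Experiment phases used in self-report / physiology tables, in protocol order.
PHASES = ("BASELINE", "CALM_STIMULUS", "CALM_DRIVE", "STRESS_STIMULUS", "STRESS_DRIVE")

CONDITIONS = ("CALM", "STRESS")
SCOPES = ("ENTIRE", "INITIAL8")


@dataclass
class SteeringTrace:
    """Timestamped signed steering-angle series.

    Attributes
    ----------
    time : ndarray
        Sample times in seconds (strictly increasing after cleaning).
    angle : ndarray
        Steering angle in degrees, signed, clockwise-positive, |angle| <= 450.
    sample_rate_nominal : float
        Nominal sensor rate in Hz; carried as metadata, never re-estimated.
    participant_id : str
    condition : str or None
        "CALM" or "STRESS" when known.
    drive_scope : str
        "ENTIRE" or "INITIAL8".
    """

    time: np.ndarray
    angle: np.ndarray
    sample_rate_nominal: float = 100.0
    participant_id: str = ""
    condition: str | None = None
    drive_scope: str = "ENTIRE"

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if self.time.shape != self.angle.shape:
            raise FormatError("time and angle must have equal length")
        if self.sample_rate_nominal <= 0:
            raise FormatError("sample_rate_nominal must be positive")
        _check_angle_range(self.angle)

    def __len__(self) -> int:
        return self.time.size

    def replace(self, **kw) -> "SteeringTrace":
        return dataclasses.replace(self, **kw)


@dataclass
class SpeedTrace:
    """Timestamped vehicle-speed series (mph)."""

    time: np.ndarray
    speed: np.ndarray
    sample_rate_nominal: float = 50.0

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        if self.time.shape != self.speed.shape:
            raise FormatError("time and speed must have equal length")
        if np.any(self.speed < 0):
            raise FormatError("speed must be non-negative")

    def __len__(self) -> int:
        return self.time.size


@dataclass
class ParticipantRecord:
    """Per-participant self-report and physiology values, keyed by phase.

    ``self_report`` maps metric name (stress, arousal, valence, tension) to a
    phase -> value dict on the study's 0-10 scale; ``hr`` (bpm) and ``rmssd``
    (ms) map phase -> value directly.
    """

    participant_id: str
    self_report: dict = field(default_factory=dict)
    hr: dict = field(default_factory=dict)
    rmssd: dict = field(default_factory=dict)

    def __post_init__(self):
        for metric, per_phase in self.self_report.items():
            for phase, v in per_phase.items():
                if not (0 <= v <= 10):
                    raise FormatError(
                        f"self-report {metric}/{phase}={v} outside [0, 10]"
                    )
        for phase, v in self.hr.items():
            if v <= 0:
                raise FormatError(f"hr/{phase}={v} must be positive")


def _check_angle_range(angle: np.ndarray) -> None:
    bad = np.flatnonzero(np.abs(angle) > MAX_ANGLE_DEG)
    if bad.size:
        i = int(bad[0])
        raise AngleRangeError(
            f"|angle| > {MAX_ANGLE_DEG} at row {i} (angle={angle[i]})"
        )


def _read_two_column_csv(path, cols: tuple[str, str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    return df


def read_steering_csv(
    path,
    participant_id: str = "",
    condition: str | None = None,
    sample_rate_nominal: float = 100.0,
) -> SteeringTrace:
    """Read a ``time_s,angle_deg`` CSV into a raw (uncleaned) SteeringTrace.

    Raises :class:`FormatError` on missing columns and
    :class:`AngleRangeError` naming the first offending row if any sample
    exceeds +/-450 degrees.
    """
    df = _read_two_column_csv(path, ("time_s", "angle_deg"))
    return SteeringTrace(
        time=df["time_s"].to_numpy(float),
        angle=df["angle_deg"].to_numpy(float),
        sample_rate_nominal=sample_rate_nominal,
        participant_id=participant_id,
        condition=condition,
    )


def write_steering_csv(trace: SteeringTrace, path) -> None:
    _check_angle_range(trace.angle)
    pd.DataFrame({"time_s": trace.time, "angle_deg": trace.angle}).to_csv(
        path, index=False
    )


def read_speed_csv(path, sample_rate_nominal: float = 50.0) -> SpeedTrace:
    df = _read_two_column_csv(path, ("time_s", "speed_mph"))
    return SpeedTrace(
        time=df["time_s"].to_numpy(float),
        speed=df["speed_mph"].to_numpy(float),
        sample_rate_nominal=sample_rate_nominal,
    )


def write_speed_csv(trace: SpeedTrace, path) -> None:
    pd.DataFrame({"time_s": trace.time, "speed_mph": trace.speed}).to_csv(
        path, index=False
    )


def clean_timestamps(trace: SteeringTrace) -> SteeringTrace:
    """Drop samples whose timestamp repeats an earlier one (first kept).

    After cleaning, time is strictly increasing.  Idempotent.  Raises
    :class:`EmptyTraceError` on an empty trace and :class:`FormatError` if the
    deduplicated times are still not increasing (an out-of-order log).
    """
    if len(trace) == 0:
        raise EmptyTraceError("cannot clean an empty trace")
    keep = np.ones(len(trace), dtype=bool)
    keep[1:] = trace.time[1:] != trace.time[:-1]
    # non-adjacent repeats: fall back to a stable first-occurrence pass
    t = trace.time[keep]
    if np.unique(t).size != t.size:
        seen: set[float] = set()
        keep = np.fromiter(
            (tt not in seen and not seen.add(tt) for tt in trace.time),
            dtype=bool,
            count=len(trace),
        )
        t = trace.time[keep]
    if np.any(np.diff(t) <= 0):
        raise FormatError("timestamps are not increasing after deduplication")
    return trace.replace(time=t, angle=trace.angle[keep])


def read_participant_table(path) -> dict[str, ParticipantRecord]:
    """Read a long-format ``participant,metric,phase,value`` CSV.

    Metric names ``hr`` and ``rmssd`` populate the physiology fields; anything
    else is treated as a 0-10 self-report scale.
    """
    df = pd.read_csv(path)
    needed = {"participant", "metric", "phase", "value"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: needs columns {sorted(needed)}")
    records: dict[str, ParticipantRecord] = {}
    for (pid,), grp in df.groupby(["participant"]):
        rec = ParticipantRecord(participant_id=str(pid))
        for _, row in grp.iterrows():
            metric, phase, value = row["metric"], row["phase"], float(row["value"])
            if metric == "hr":
                rec.hr[phase] = value
            elif metric == "rmssd":
                rec.rmssd[phase] = value
            else:
                rec.self_report.setdefault(metric, {})[phase] = value
        records[str(pid)] = ParticipantRecord(
            rec.participant_id, rec.self_report, rec.hr, rec.rmssd
        )
    return records


def write_participant_table(records: dict[str, ParticipantRecord], path) -> None:
    rows = []
    for pid, rec in records.items():
        for metric, per_phase in rec.self_report.items():
            for phase, v in per_phase.items():
                rows.append((pid, metric, phase, v))
        for metric, per_phase in (("hr", rec.hr), ("rmssd", rec.rmssd)):
            for phase, v in per_phase.items():
                rows.append((pid, metric, phase, v))
    pd.DataFrame(rows, columns=["participant", "metric", "phase", "value"]).to_csv(
        path, index=False
    )


def load_manifest(path) -> dict:
    """Load a YAML/JSON manifest mapping participant ids to file paths and labels."""
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict):
        raise FormatError(f"{path}: manifest must be a mapping")
    base = Path(path).parent
    manifest.setdefault("base_dir", str(base))
    return manifest
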