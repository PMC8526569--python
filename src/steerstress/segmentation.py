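"""Turn segmentation of absolute steering-angle traces.

A *turn segment* is one monotonically non-decreasing excursion of the
absolute steering angle from a valley (local minimum) to the next peak
(local maximum).  Segments smaller than a lower amplitude bound (default
40 degrees — excursions too small to engage the large arm/shoulder muscle
groups) are discarded, and segments exceeding an upper bound (default
150 degrees, where drivers re-grip the wheel and inject a second steering
impulse) are truncated at the bound.  Both bounds are measured relative to
the segment's valley, i.e. on the excursion since turn start.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .canbus_io import SpeedTrace, SteeringTrace
from .errors import InsufficientDataError

__all__ = [
    "SegmentationParams",
    "TurnSegment",
    "to_absolute",
    "extract_segments",
    "restrict_to_initial_window",
    "driving_behaviour_metrics",
    "segments_to_frame",
    "truncate_segment",
    "monotone_runs",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Segmentation thresholds, all in degrees except the time window.

    ``lower_bound``: minimum amplitude (peak - valley) for a segment to be
    retained.  ``upper_bound``: excursion above the valley at which the
    segment is truncated; ``inf`` disables truncation.  ``initial_window_s``:
    duration of the drive-start window used for the rapid (first-turns)
    analysis scope.
    """

    lower_bound: float = 40.0
    upper_bound: float = 150.0
    initial_window_s: float = 110.0

    def __post_init__(self):
        if not (0 < self.lower_bound < self.upper_bound <= 450.0) and not (
            0 < self.lower_bound and np.isinf(self.upper_bound)
        ):
            raise ValueError(
                "require 0 < lower_bound < upper_bound <= 450 "
                f"(got {self.lower_bound}, {self.upper_bound})"
            )


@dataclass
class TurnSegment:
    """One valley-to-peak excursion of absolute steering angle.

    ``samples`` holds the retained absolute angles (non-decreasing);
    ``amplitude`` is peak - valley *before* truncation, so the lower-bound
    filter and the reported turn size are unaffected by the upper bound.
    """

    participant_id: str
    condition: str | None
    start_time: float
    end_time: float
    times: np.ndarray
    samples: np.ndarray
    valley_angle: float
    peak_angle: float
    amplitude: float
    truncated: bool
    mean_speed: float | None = None

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time

    def __len__(self) -> int:
        return self.samples.size

    def replace(self, **kw) -> "TurnSegment":
        return dataclasses.replace(self, **kw)


def to_absolute(trace: SteeringTrace) -> SteeringTrace:
    """Fold the signed (clockwise-positive) angle into absolute degrees."""
    return trace.replace(angle=np.abs(trace.angle))


def monotone_runs(x: np.ndarray) -> list[tuple[int, int]]:
    """Maximal non-decreasing runs of ``x`` as (valley_idx, peak_idx) pairs.

    Plateaus belong to the surrounding run; a trailing plateau at the top of
    a run is cut at its first sample (peak ties break toward the earlier
    index).  Boundary samples count as extrema, so a drive that starts
    mid-maneuver still yields its opening rise.
    """
    n = x.size
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n - 1:
        if x[i + 1] < x[i]:
            i += 1
            continue
        j = i
        while j < n - 1 and x[j + 1] >= x[j]:
            j += 1
        peak = j
        while peak > i and x[peak - 1] == x[peak]:
            peak -= 1
        if x[peak] > x[i]:
            runs.append((i, peak))
        i = j
    return runs


def truncate_segment(
    times: np.ndarray, samples: np.ndarray, valley: float, upper_bound: float
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Cut a run at the first sample whose excursion exceeds ``upper_bound``.

    The crossing sample itself is excluded; returns (times, samples,
    truncated).
    """
    over = np.flatnonzero(samples - valley > upper_bound)
    if over.size == 0:
        return times, samples, False
    cut = int(over[0])
    return times[:cut], samples[:cut], True


def extract_segments(
    trace: SteeringTrace, params: SegmentationParams = SegmentationParams()
) -> list[TurnSegment]:
    """Segment an absolute-valued, time-cleaned trace into turn segments.

    Every maximal non-decreasing run from valley to peak with amplitude
    (peak - valley) >= ``lower_bound`` is retained and truncated at
    ``upper_bound`` excursion.  Segments are time-ordered and non-overlapping.
    """
    if len(trace) < 3:
        raise InsufficientDataError(
            f"need at least 3 samples to segment, got {len(trace)}"
        )
    x = trace.angle
    segments = []
    for i, j in monotone_runs(x):
        valley, peak = float(x[i]), float(x[j])
        if peak - valley < params.lower_bound:
            continue
        times, samples, truncated = truncate_segment(
            trace.time[i : j + 1], x[i : j + 1], valley, params.upper_bound
        )
        if samples.size < 2:
            continue
        segments.append(
            TurnSegment(
                participant_id=trace.participant_id,
                condition=trace.condition,
                start_time=float(times[0]),
                end_time=float(times[-1]),
                times=times.copy(),
                samples=samples.astype(float).copy(),
                valley_angle=valley,
                peak_angle=peak,
                amplitude=peak - valley,
                truncated=truncated,
            )
        )
    return segments


def restrict_to_initial_window(
    segments: list[TurnSegment], params: SegmentationParams = SegmentationParams()
) -> list[TurnSegment]:
    """Keep segments starting inside the initial drive window.

    The rapid analysis scope (nominally the first eight turns) is implemented
    as a time window — segments with ``start_time`` below
    ``params.initial_window_s`` — because the number of turns completed in a
    fixed early interval varies between drives.  Trace time is assumed to
    start at the drive start (time zero).
    """
    return [s for s in segments if s.start_time < params.initial_window_s]


def driving_behaviour_metrics(
    segments: list[TurnSegment], speed: SpeedTrace
) -> pd.DataFrame:
    """Per-segment mean speed (mph) and duration (s).

    ``mean_speed`` averages the speed samples with time in
    [start_time, end_time]; a segment with no in-span speed sample gets NaN
    (flagged missing, never zero).  Also writes ``mean_speed`` back onto the
    segment objects.
    """
    rows = []
    for seg in segments:
        in_span = (speed.time >= seg.start_time) & (speed.time <= seg.end_time)
        mean_speed = float(np.mean(speed.speed[in_span])) if in_span.any() else np.nan
        seg.mean_speed = None if np.isnan(mean_speed) else mean_speed
        rows.append(
            {
                "participant": seg.participant_id,
                "condition": seg.condition,
                "start_time": seg.start_time,
                "duration": seg.duration,
                "mean_speed": mean_speed,
                "speed_missing": not bool(in_span.any()),
            }
        )
    return pd.DataFrame(rows)


def segments_to_frame(segments: list[TurnSegment]) -> pd.DataFrame:
    """One row per segment, ready for CSV interchange."""
    return pd.DataFrame(
        [
            {
                "participant": s.participant_id,
                "condition": s.condition,
                "start_time": s.start_time,
                "end_time": s.end_time,
                "valley": s.valley_angle,
                "peak": s.peak_angle,
                "amplitude": s.amplitude,
                "truncated": s.truncated,
                "duration": s.duration,
                "mean_speed": s.mean_speed,
            }
            for s in segments
        ]
    )
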