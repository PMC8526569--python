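"""Automatic turn-segmentation sweep and individualized binary stress decision.

The empirical 150-degree upper bound requires video coding, so the
individualized method replaces it with a data-driven sweep: the pipeline is
run for upper bounds rising in 10-degree steps until the maximum observed
turn amplitude is reached, recording per bound and condition the mean LPC
residual variance, the number of retained segments, and the damped-frequency
values.  The decision rule then

1. finds the upper bound maximizing the average segment count (averaged
   over the two conditions; ties toward the smaller bound),
2. selects the first quartile of the remaining bound range above that peak,
   and
3. labels as STRESS the condition with the larger median damped natural
   frequency pooled over all (segment, bound) pairs inside that interval —
   higher muscle stiffness raises the damped frequency.

Pooling omegas across a bound interval, rather than reading one bound,
trades single-point sensitivity against Type II errors from an unlucky
bound choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .canbus_io import SteeringTrace, clean_timestamps
from .errors import SegmentDropped, SweepEmptyError
from .lpc_msd import DEFAULT_ORDER, segment_pipeline
from .quality_filter import tukey_upper_fence, apply_threshold
from .segmentation import SegmentationParams, extract_segments, to_absolute

__all__ = [
    "SweepResult",
    "StressDecision",
    "run_sweep",
    "find_count_peak",
    "select_quartile_interval",
    "classify",
    "detect_stress",
]


@dataclass
class SweepResult:
    """Per-upper-bound pipeline summaries for two labelled conditions.

    ``upper_bounds`` ascends in constant ``step``-degree increments.  For
    each condition label, ``mean_resid_var[label][i]``, ``counts[label][i]``
    and ``omegas[label][i]`` summarize the filtered estimates at
    ``upper_bounds[i]``.
    """

    upper_bounds: np.ndarray
    step: float
    labels: tuple[str, str]
    mean_resid_var: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    omegas: dict = field(default_factory=dict)

    def average_counts(self) -> np.ndarray:
        """Segment count per bound averaged over the two conditions."""
        a, b = self.labels
        return (np.asarray(self.counts[a], float) + np.asarray(self.counts[b], float)) / 2.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label in self.labels:
            for i, ub in enumerate(self.upper_bounds):
                om = self.omegas[label][i]
                rows.append(
                    {
                        "upper_bound": float(ub),
                        "condition": label,
                        "mean_resid_var": self.mean_resid_var[label][i],
                        "avg_count": self.counts[label][i],
                        "n_omega": len(om),
                        "median_omega": float(np.median(om)) if om else np.nan,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class StressDecision:
    """Outcome of the individualized median-omega comparison."""

    participant_id: str
    peak_upper_bound: float
    selection_interval: tuple[float, float]
    medians: dict
    stress_label: str | None  # None when undecidable
    undecidable_reason: str | None = None

    @property
    def decided(self) -> bool:
        return self.stress_label is not None


def _prepare(trace: SteeringTrace) -> SteeringTrace:
    return to_absolute(clean_timestamps(trace))


def run_sweep(
    traces: dict[str, SteeringTrace],
    lower_bound: float = 40.0,
    step: float = 10.0,
    order: int = DEFAULT_ORDER,
    root_mapping: str = "literal",
    fitting_threshold: float | str = "auto",
) -> SweepResult:
    """Run segmentation + LPC + quality filtering over an upper-bound grid.

    ``traces`` maps two condition labels to raw steering traces (cleaning
    and the absolute transform are applied here).  Upper bounds run from
    ``lower_bound + step`` in ``step`` increments until the maximum observed
    turn amplitude is covered.  ``fitting_threshold`` is either a number
    (e.g. a cohort-level threshold) applied at every sweep point, or
    ``"auto"``: at each sweep point the minimum of the per-condition Tukey
    upper fences on residual variance (falling back to a pooled fence, or no
    filtering, when a condition has fewer than four fits).
    """
    if len(traces) != 2:
        raise ValueError(f"need exactly two condition traces, got {len(traces)}")
    labels = tuple(traces)
    prepared = {lab: _prepare(tr) for lab, tr in traces.items()}
    base_params = SegmentationParams(
        lower_bound=lower_bound, upper_bound=float("inf")
    )
    base_segments = {
        lab: extract_segments(tr, base_params) for lab, tr in prepared.items()
    }
    amplitudes = [s.amplitude for segs in base_segments.values() for s in segs]
    if not amplitudes:
        raise SweepEmptyError("no segments above the lower bound in either trace")
    max_amp = max(amplitudes)
    n_steps = int(np.ceil((max_amp - lower_bound) / step))
    upper_bounds = lower_bound + step * np.arange(1, max(n_steps, 1) + 1)

    result = SweepResult(
        upper_bounds=upper_bounds, step=step, labels=labels,
        mean_resid_var={lab: [] for lab in labels},
        counts={lab: [] for lab in labels},
        omegas={lab: [] for lab in labels},
    )
    # A segment truncated at two bounds beyond its amplitude is the same
    # series, so fits are cached per distinct cut index.
    caches = {
        lab: [
            _TruncationCache(seg, upper_bounds, order, root_mapping)
            for seg in base_segments[lab]
        ]
        for lab in labels
    }
    any_segments = False
    for bi, ub in enumerate(upper_bounds):
        per_label = {
            lab: [e for c in caches[lab] if (e := c.estimate(bi)) is not None]
            for lab in labels
        }
        pooled = [e.residual_variance for ests in per_label.values() for e in ests]
        threshold = _resolve_threshold(fitting_threshold, per_label, pooled)
        for lab in labels:
            ests = per_label[lab]
            if threshold is not None:
                ests, _, _ = apply_threshold(ests, threshold)
            result.mean_resid_var[lab].append(
                float(np.mean([e.residual_variance for e in ests])) if ests else np.nan
            )
            result.counts[lab].append(len(ests))
            result.omegas[lab].append([e.omega for e in ests])
            any_segments = any_segments or bool(ests)
    if not any_segments:
        raise SweepEmptyError("quality filtering removed all segments at every bound")
    return result


class _TruncationCache:
    """Per-segment LPC fits keyed by truncation cut index over a bound grid."""

    def __init__(self, seg, upper_bounds, order, root_mapping):
        self._seg = seg
        self._order = order
        self._root_mapping = root_mapping
        excursion = seg.samples - seg.valley_angle
        # first index exceeding each bound == truncation cut (samples ascend)
        self._cuts = np.searchsorted(excursion, upper_bounds, side="right")
        self._fits: dict[int, object] = {}

    def estimate(self, bound_index: int):
        cut = int(self._cuts[bound_index])
        if cut not in self._fits:
            self._fits[cut] = self._fit(cut)
        return self._fits[cut]

    def _fit(self, cut: int):
        seg = self._seg
        if cut < 2:
            return None
        truncated = cut < seg.samples.size
        trunc = seg.replace(
            times=seg.times[:cut],
            samples=seg.samples[:cut],
            truncated=truncated,
            end_time=float(seg.times[cut - 1]),
        )
        try:
            return segment_pipeline(
                trunc, order=self._order, root_mapping=self._root_mapping
            )
        except SegmentDropped:
            return None


def _resolve_threshold(spec, per_label: dict, pooled: list) -> float | None:
    if spec != "auto":
        return float(spec)
    fences = [
        tukey_upper_fence([e.residual_variance for e in ests])
        for ests in per_label.values()
        if len(ests) >= 4
    ]
    if len(fences) == len(per_label):
        return min(fences)
    if len(pooled) >= 4:
        return tukey_upper_fence(pooled)
    return None


def find_count_peak(sweep: SweepResult) -> float:
    """Upper bound maximizing the condition-averaged segment count.

    Ties break toward the smallest bound.
    """
    avg = sweep.average_counts()
    return float(sweep.upper_bounds[int(np.argmax(avg))])


def select_quartile_interval(
    sweep: SweepResult, peak_upper_bound: float
) -> tuple[float, float]:
    """First quartile of the remaining bound range above the count peak.

    Returns [peak, peak + (max_bound - peak)/4], the upper edge snapped up
    to the sweep grid; degenerates to [max, max] when the peak is the final
    sweep point.
    """
    max_bound = float(sweep.upper_bounds[-1])
    if peak_upper_bound >= max_bound:
        return (max_bound, max_bound)
    hi = peak_upper_bound + (max_bound - peak_upper_bound) / 4.0
    grid = sweep.upper_bounds
    hi = float(grid[np.searchsorted(grid, hi - 1e-9)])
    return (float(peak_upper_bound), hi)


def classify(
    sweep: SweepResult,
    interval: tuple[float, float],
    participant_id: str = "",
    tie_policy: str = "undecided",
) -> StressDecision:
    """Label as STRESS the condition with the larger median omega in the interval.

    Each condition's omega pool collects one value per (segment, bound) pair
    whose sweep upper bound lies in ``interval``.  An empty pool on either
    side, or a median tie under the default ``tie_policy="undecided"``, gives
    an undecided result (never a silent guess); ``tie_policy`` may name a
    condition label to prefer when sensitivity matters more than specificity.
    """
    lo, hi = interval
    in_int = (sweep.upper_bounds >= lo - 1e-9) & (sweep.upper_bounds <= hi + 1e-9)
    pools = {
        lab: [w for i in np.flatnonzero(in_int) for w in sweep.omegas[lab][i]]
        for lab in sweep.labels
    }
    peak = lo
    empty = [lab for lab, pool in pools.items() if not pool]
    if empty:
        return StressDecision(
            participant_id, peak, interval,
            {lab: (float(np.median(p)) if p else float("nan")) for lab, p in pools.items()},
            stress_label=None,
            undecidable_reason=f"no omega values in interval for {empty}",
        )
    medians = {lab: float(np.median(pool)) for lab, pool in pools.items()}
    a, b = sweep.labels
    if medians[a] > medians[b]:
        label = a
    elif medians[b] > medians[a]:
        label = b
    elif tie_policy in sweep.labels:
        label = tie_policy
    else:
        return StressDecision(
            participant_id, peak, interval, medians,
            stress_label=None, undecidable_reason="median tie",
        )
    return StressDecision(participant_id, peak, interval, medians, stress_label=label)


def detect_stress(
    traces: dict[str, SteeringTrace],
    lower_bound: float = 40.0,
    step: float = 10.0,
    order: int = DEFAULT_ORDER,
    root_mapping: str = "literal",
    fitting_threshold: float | str = "auto",
    tie_policy: str = "undecided",
    participant_id: str = "",
) -> tuple[StressDecision, SweepResult]:
    """End-to-end individualized decision: sweep, peak, interval, classify."""
    sweep = run_sweep(
        traces, lower_bound=lower_bound, step=step, order=order,
        root_mapping=root_mapping, fitting_threshold=fitting_threshold,
    )
    peak = find_count_peak(sweep)
    interval = select_quartile_interval(sweep, peak)
    decision = classify(
        sweep, interval, participant_id=participant_id, tie_policy=tie_policy
    )
    return decision, sweep
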