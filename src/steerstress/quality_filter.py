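"""Residual-variance quality filtering of LPC fits via Tukey upper fences.

Poorly fitted segments are removed by an anomaly threshold on the LPC
residual-error variance: within each condition-by-scope group (CALM/STRESS
x ENTIRE/INITIAL8) the Tukey upper fence Q3 + 1.5*(Q3 - Q1) is computed on
the pooled residual variances, and the minimum of the group fences is the
overall fitting threshold.  Values exactly at the threshold are kept (<=
convention); only the upper fence applies, since a low residual variance
means a good fit and is never anomalous here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import InsufficientDataError, MissingGroupError
from .lpc_msd import MsdEstimate

__all__ = [
    "FitThreshold",
    "tukey_upper_fence",
    "compute_fitting_threshold",
    "apply_threshold",
    "DEFAULT_GROUPS",
]

#: The four condition-by-scope groups whose fences feed the overall threshold.
DEFAULT_GROUPS = (
    ("CALM", "ENTIRE"),
    ("STRESS", "ENTIRE"),
    ("CALM", "INITIAL8"),
    ("STRESS", "INITIAL8"),
)


@dataclass(frozen=True)
class FitThreshold:
    """Per-group Tukey upper fences and their minimum, the overall threshold."""

    group_fences: dict
    overall_threshold: float

    def to_dict(self) -> dict:
        return {
            "group_fences": {"/".join(k): v for k, v in self.group_fences.items()},
            "overall_threshold": self.overall_threshold,
        }


def tukey_upper_fence(
    values: Sequence[float], quartile_method: str = "linear"
) -> float:
    """Tukey upper fence Q3 + 1.5 * IQR of ``values``.

    Quartiles use linear interpolation between order statistics by default;
    alternative hinge conventions shift the fence, so the method is exposed
    (any :func:`numpy.quantile` interpolation name).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 4:
        raise InsufficientDataError(
            f"need >= 4 finite values for a Tukey fence, got {v.size}"
        )
    q1, q3 = np.quantile(v, [0.25, 0.75], method=quartile_method)
    return float(q3 + 1.5 * (q3 - q1))


def compute_fitting_threshold(
    grouped_variances: dict,
    expected_groups: Iterable = DEFAULT_GROUPS,
    quartile_method: str = "linear",
) -> FitThreshold:
    """Overall fitting threshold = minimum of the per-group upper fences.

    ``grouped_variances`` maps (condition, scope) to the pooled residual
    variances of that group.  Raises :class:`MissingGroupError` listing any
    expected group that is absent.
    """
    expected = list(expected_groups)
    missing = [g for g in expected if g not in grouped_variances]
    if missing:
        raise MissingGroupError(f"missing condition/scope groups: {missing}")
    fences = {
        g: tukey_upper_fence(grouped_variances[g], quartile_method) for g in expected
    }
    return FitThreshold(
        group_fences=fences, overall_threshold=float(min(fences.values()))
    )


def _residual_variance(item) -> float:
    if isinstance(item, MsdEstimate):
        return item.residual_variance
    return float(item)


def apply_threshold(
    estimates: Sequence, threshold: float
) -> tuple[list, list, float]:
    """Partition estimates into (kept, removed) by residual variance.

    Estimates with residual_variance <= threshold are kept; strictly greater
    are removed.  Accepts :class:`MsdEstimate` objects or bare variances.
    Returns (kept, removed, removed_fraction).
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    estimates = list(estimates)
    kept = [e for e in estimates if _residual_variance(e) <= threshold]
    removed = [e for e in estimates if _residual_variance(e) > threshold]
    frac = len(removed) / len(estimates) if estimates else 0.0
    return kept, removed, frac
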