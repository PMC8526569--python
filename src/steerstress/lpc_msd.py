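"""LPC inference of mass-spring-damper parameters from turn segments.

A rapid goal-directed steering movement is modelled as the step response of
an underdamped second-order mass-spring-damper (MSD) system: the mass
aggregates arm, hand and wheel; the spring is the muscle tension; the damper
the total friction.  Because only the output movement is observed, the
system is identified by inverse filtering: an order-``p`` linear predictive
coding (LPC) model (default p = 4) is fitted by the autocorrelation method,
and the complex roots ``r`` of the prediction-error polynomial characterize
the resonance.  The damped natural frequency is read off as
``omega = |Im(r)|`` and the damping ratio as ``zeta = |Re(r)| / |r|`` of the
dominant complex root.  ``omega`` is a dimensionless per-sample quantity on
this convention; the method only needs within-subject contrasts, which any
monotone frequency surrogate preserves.  An alternative log mapping of the
roots into the Laplace (s-) plane is available via ``root_mapping="log"``.

Segments are min-max normalized to [0, 1] before fitting so that one global
residual-variance threshold is meaningful across segments of different
amplitude; this also makes omega and zeta exactly invariant to affine
rescaling of the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    ConditioningError,
    DegenerateSegmentError,
    InsufficientDataError,
    NoOscillatoryModeError,
    SegmentDropped,
)
from .segmentation import TurnSegment

__all__ = [
    "LpcFit",
    "MsdEstimate",
    "normalize_segment",
    "autocorrelation",
    "levinson_durbin",
    "fit_lpc",
    "extract_msd",
    "segment_pipeline",
]

DEFAULT_ORDER = 4


@dataclass
class LpcFit:
    """Order-p LPC fit: prediction coefficients, residual variance, roots.

    ``coefficients`` are the a_k in x[n] ~ sum_k a_k x[n-k];
    ``residual_variance`` is the variance of the one-step prediction error
    over the predictable samples of the normalized segment; ``roots`` are the
    p complex roots of z^p - a_1 z^{p-1} - ... - a_p (conjugate pairs, since
    the coefficients are real).
    """

    order: int
    coefficients: np.ndarray
    residual_variance: float
    roots: np.ndarray


@dataclass
class MsdEstimate:
    """MSD parameters recovered from one segment's LPC fit."""

    omega: float
    zeta: float
    selected_root: complex
    residual_variance: float
    segment: TurnSegment | None = None


def normalize_segment(samples) -> np.ndarray:
    """Min-max scale a segment's samples to [0, 1].

    Raises :class:`DegenerateSegmentError` for a constant segment.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("need >= 2 samples to normalize")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateSegmentError("constant segment cannot be min-max scaled")
    return (x - lo) / (hi - lo)


def autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocorrelation r[0..max_lag] of ``x``.

    The biased (1/N) estimator is the one for which Levinson-Durbin is
    guaranteed stable.
    """
    n = x.size
    r = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        r[k] = np.dot(x[: n - k], x[k:]) / n
    return r


def levinson_durbin(r: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve the Toeplitz Yule-Walker system R a = r[1:] by Levinson recursion.

    Parameters
    ----------
    r : autocorrelation sequence r[0..p].

    Returns
    -------
    a : forward prediction coefficients (length p).
    err : final prediction-error power.
    """
    p = r.size - 1
    if r[0] <= 0:
        raise ConditioningError("zero-power series: autocorrelation r[0] <= 0")
    a = np.zeros(p)
    err = r[0]
    for i in range(1, p + 1):
        acc = r[i] - np.dot(a[: i - 1], r[i - 1 : 0 : -1])
        if err <= 0:
            raise ConditioningError("singular autocorrelation matrix")
        k = acc / err
        a_prev = a[: i - 1].copy()
        a[: i - 1] = a_prev - k * a_prev[::-1]
        a[i - 1] = k
        err *= 1.0 - k * k
    return a, float(err)


def fit_lpc(series, order: int = DEFAULT_ORDER) -> LpcFit:
    """Fit an order-p LPC model by the autocorrelation method.

    The coefficients minimize the mean squared one-step-ahead prediction
    error under the autocorrelation (windowed) formulation; the reported
    ``residual_variance`` is the variance of (observed - predicted) over
    samples order..N-1.
    """
    x = np.asarray(series, dtype=float)
    if x.size <= order:
        raise InsufficientDataError(
            f"series length {x.size} must exceed LPC order {order}"
        )
    if np.ptp(x) == 0:
        raise DegenerateSegmentError("constant series has no LPC model")
    r = autocorrelation(x, order)
    a, _ = levinson_durbin(r)
    predicted = np.zeros(x.size - order)
    for k in range(1, order + 1):
        predicted += a[k - 1] * x[order - k : x.size - k]
    resid = x[order:] - predicted
    roots = np.roots(np.concatenate(([1.0], -a)))
    return LpcFit(
        order=order,
        coefficients=a,
        residual_variance=float(np.var(resid)),
        roots=roots,
    )


def extract_msd(
    fit: LpcFit, root_mapping: str = "literal", imag_tol: float = 1e-9
) -> MsdEstimate:
    """Read omega and zeta off the dominant complex root of an LPC fit.

    Among roots with positive imaginary part the dominant one — largest
    modulus, i.e. the slowest-decaying, physically persistent mode — is
    selected; modulus ties break toward the smaller |Im(r)|.  With the
    default ``root_mapping="literal"``, omega = |Im(r)| and
    zeta = |Re(r)| / |r| are applied to the z-plane root directly.  With
    ``"log"`` the root is first mapped to the s-plane via s = log(r)
    (per-sample units) and the same formulas applied to s.

    Raises :class:`NoOscillatoryModeError` when every root is real.
    """
    cand = fit.roots[fit.roots.imag > imag_tol]
    if cand.size == 0:
        raise NoOscillatoryModeError("all prediction-polynomial roots are real")
    # dominant root; exact modulus ties break toward the smaller |Im|
    order_keys = sorted(
        range(cand.size), key=lambda i: (-abs(cand[i]), abs(cand[i].imag))
    )
    root = cand[order_keys[0]]
    if root_mapping == "log":
        mapped = np.log(root)
    elif root_mapping == "literal":
        mapped = root
    else:
        raise ValueError(f"unknown root_mapping {root_mapping!r}")
    omega = abs(mapped.imag)
    zeta = abs(mapped.real) / abs(mapped)
    return MsdEstimate(
        omega=float(omega),
        zeta=float(zeta),
        selected_root=complex(root),
        residual_variance=fit.residual_variance,
    )


def segment_pipeline(
    segment: TurnSegment,
    order: int = DEFAULT_ORDER,
    root_mapping: str = "literal",
) -> MsdEstimate:
    """Normalize -> fit LPC -> extract MSD for one turn segment.

    Failures surface as :class:`SegmentDropped` with a machine-readable
    reason (``degenerate``, ``too_short``, ``no_oscillatory_mode``,
    ``ill_conditioned``) so callers can log and continue.
    """
    try:
        series = normalize_segment(segment.samples)
        fit = fit_lpc(series, order=order)
        est = extract_msd(fit, root_mapping=root_mapping)
    except DegenerateSegmentError as e:
        raise SegmentDropped("degenerate", str(e)) from e
    except InsufficientDataError as e:
        raise SegmentDropped("too_short", str(e)) from e
    except NoOscillatoryModeError as e:
        raise SegmentDropped("no_oscillatory_mode", str(e)) from e
    except ConditioningError as e:
        raise SegmentDropped("ill_conditioned", str(e)) from e
    est.segment = segment
    return est
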