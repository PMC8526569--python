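"""Cohort-level validation statistics.

Normalization and baseline correction of self-report/physiology tables,
within-subject permutation t-tests (sign-flip null, proportion-based P),
Bonferroni correction, Cohen's d, Pearson correlation, and RMSSD.

The permutation test follows the study design: each participant contributes
a paired (condition A, condition B) value; under the null the two labels
are exchangeable within participant, so the null distribution is generated
by independently flipping the sign of each participant's paired difference.
``P`` is the fraction of permuted t statistics at least as extreme as the
observed one — a proportion over the permutations drawn, not a parametric
p-value.  A full across-participant shuffle mode is available behind
``scheme="shuffle"``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .errors import InsufficientDataError, UndefinedEffectError

__all__ = [
    "PermutationResult",
    "minmax_baseline",
    "paired_t",
    "permutation_ttest",
    "exhaustive_signflip_p",
    "bonferroni",
    "cohens_d",
    "pearson_r",
    "rmssd",
]

DEFAULT_N_PERMUTATIONS = 100_000
#: Planned comparisons in the stimulus-validation analysis set
#: (stimulus vs stimulus, drive vs drive, and each stimulus vs its drive).
DEFAULT_N_COMPARISONS = 4


@dataclass
class PermutationResult:
    """Outcome of a within-subject permutation t-test."""

    t_observed: float
    n_permutations: int
    p: float
    p_adjusted: float | None
    cohens_d: float | None
    seed: int | None
    alternative: str
    scheme: str = "sign_flip"


def minmax_baseline(table: pd.DataFrame) -> pd.DataFrame:
    """Min-max normalize per participant and metric, then subtract baseline.

    ``table`` is long-format with columns participant, metric, phase, value
    and must contain a ``BASELINE`` phase for every participant x metric.
    Values are scaled to [0, 1] across that participant's phases, then the
    scaled baseline is subtracted, so the corrected baseline is exactly 0 and
    all corrected values lie in [-1, 1].  A metric constant across phases
    normalizes to all-zero.
    """
    needed = {"participant", "metric", "phase", "value"}
    if not needed.issubset(table.columns):
        raise ValueError(f"table needs columns {sorted(needed)}")
    out = table.copy()
    out["normalized"] = np.nan
    for (pid, metric), grp in table.groupby(["participant", "metric"]):
        phases = dict(zip(grp["phase"], grp["value"]))
        if "BASELINE" not in phases:
            raise InsufficientDataError(
                f"participant {pid} metric {metric} lacks a BASELINE phase"
            )
        v = grp["value"].to_numpy(float)
        lo, hi = v.min(), v.max()
        if hi == lo:
            scaled = np.zeros_like(v)
        else:
            scaled = (v - lo) / (hi - lo)
        base = scaled[(grp["phase"] == "BASELINE").to_numpy()][0]
        out.loc[grp.index, "normalized"] = scaled - base
    return out


def paired_t(a: np.ndarray, b: np.ndarray) -> float:
    """Paired-samples t statistic of a - b (0 when the differences are constant-zero)."""
    d = np.asarray(a, float) - np.asarray(b, float)
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(d.mean() / (sd / np.sqrt(d.size)))


def _t_from_diffs(d: np.ndarray, axis: int = -1) -> np.ndarray:
    n = d.shape[axis]
    sd = d.std(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = d.mean(axis=axis) / (sd / np.sqrt(n))
    return np.where(sd == 0, 0.0, t)


def permutation_ttest(
    a,
    b,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | None = None,
    alternative: str = "directional",
    scheme: str = "sign_flip",
    n_comparisons: int | None = None,
) -> PermutationResult:
    """Within-subject permutation t-test on paired per-participant values.

    Parameters
    ----------
    a, b : per-participant values for the two conditions (equal length >= 2).
    alternative : "directional" reports the one-sided P in the direction of
        the observed t (the 95%/5% significance reading); "greater"/"less"
        fix the direction of a - b a priori; "two-sided" doubles nothing —
        it counts |t*| >= |t|.
    scheme : "sign_flip" flips each participant's paired difference
        (the exchangeable within-subject null); "shuffle" re-pairs the pooled
        values across participants.
    n_comparisons : when given, a Bonferroni-adjusted P is reported too.

    P is the proportion of permuted statistics at least as extreme as the
    observed one; zero-variance differences are degenerate and reported with
    t = 0, P = 1.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D arrays")
    n = a.size
    if n < 2:
        raise InsufficientDataError("need >= 2 participants with both conditions")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    d = a - b
    try:
        effect = cohens_d(a, b)
    except UndefinedEffectError:
        effect = None

    if d.std(ddof=1) == 0:
        # constant differences: the paired t is undefined, so the test is
        # degenerate and reported as uninformative (t = 0, P = 1)
        res = PermutationResult(0.0, n_permutations, 1.0, None, effect, seed,
                                alternative, scheme)
        if n_comparisons:
            res.p_adjusted = bonferroni(res.p, n_comparisons)
        return res

    t_obs = paired_t(a, b)
    rng = np.random.default_rng(seed)
    if scheme == "sign_flip":
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
        t_perm = _t_from_diffs(signs * d)
    elif scheme == "shuffle":
        pooled = np.concatenate([a, b])
        t_perm = np.empty(n_permutations)
        for i in range(n_permutations):
            perm = rng.permutation(pooled)
            t_perm[i] = paired_t(perm[:n], perm[n:])
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    if alternative == "directional":
        p = float(np.mean(t_perm >= t_obs) if t_obs >= 0 else np.mean(t_perm <= t_obs))
    elif alternative == "greater":
        p = float(np.mean(t_perm >= t_obs))
    elif alternative == "less":
        p = float(np.mean(t_perm <= t_obs))
    elif alternative == "two-sided":
        p = float(np.mean(np.abs(t_perm) >= abs(t_obs)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")

    res = PermutationResult(t_obs, n_permutations, p, None, effect, seed,
                            alternative, scheme)
    if n_comparisons:
        res.p_adjusted = bonferroni(p, n_comparisons)
    return res


def exhaustive_signflip_p(a, b, alternative: str = "directional") -> float:
    """Exact sign-flip P by enumerating all 2^n sign assignments (small n)."""
    d = np.asarray(a, float) - np.asarray(b, float)
    n = d.size
    if n > 20:
        raise ValueError("exhaustive enumeration is for small n (<= 20)")
    t_obs = paired_t(a, b)
    t_all = np.array(
        [_t_from_diffs(np.array(s) * d) for s in itertools.product((-1.0, 1.0), repeat=n)]
    )
    if alternative == "directional":
        return float(
            np.mean(t_all >= t_obs) if t_obs >= 0 else np.mean(t_all <= t_obs)
        )
    if alternative == "greater":
        return float(np.mean(t_all >= t_obs))
    if alternative == "less":
        return float(np.mean(t_all <= t_obs))
    if alternative == "two-sided":
        return float(np.mean(np.abs(t_all) >= abs(t_obs)))
    raise ValueError(f"unknown alternative {alternative!r}")


def bonferroni(p: float, n_comparisons: int = DEFAULT_N_COMPARISONS) -> float:
    """Bonferroni-adjusted probability min(1, p * m)."""
    return min(1.0, p * n_comparisons)


def cohens_d(group_a, group_b) -> float:
    """Cohen's d with the pooled (n-1) standard deviation."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("both groups need >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2))
    if pooled == 0:
        raise UndefinedEffectError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / pooled)


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length series."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise InsufficientDataError("need equal lengths >= 3")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedEffectError("zero variance: correlation undefined")
    return float(sp_stats.pearsonr(x, y).statistic)


def rmssd(rr_intervals) -> float:
    """Root mean square of successive differences of RR intervals (ms).

    The time-domain heart-rate-variability measure expected to drop under
    stress.
    """
    rr = np.asarray(rr_intervals, float)
    if rr.size < 2:
        raise InsufficientDataError("need >= 2 RR intervals")
    return float(np.sqrt(np.mean(np.diff(rr) ** 2)))
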