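"""Resampling confidence intervals for the paired-ordinal measures.

Default is a subject-level percentile bootstrap (B = 2000).  Because every
table-based measure depends on the data only through the cell counts,
resampling n subjects with replacement is carried out as multinomial
resampling of the contingency table, which lets all B replicate tables be
evaluated by one vectorised kernel call.  A leave-one-out jackknife with a
normal approximation is available as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import PairedAssessments, contingency_from_pairs
from .measures import (
    MEASURE_RANGES,
    MeasureValue,
    measure_from_counts,
    measure_from_pairs,
)

__all__ = ["ResamplingPlan", "resample_ci", "significant_shift"]


@dataclass(frozen=True)
class ResamplingPlan:
    """How to build a confidence interval.

    method
        ``"bootstrap"`` (percentile, subject-level) or ``"jackknife"``
        (leave-one-out pseudo-values with a normal approximation).
    replicates
        Bootstrap replicate count B (ignored by the jackknife).
    level
        Confidence level in (0.5, 1); default 0.95.
    seed
        Required for the bootstrap; no hidden global randomness.
    """

    method: str = "bootstrap"
    replicates: int = 2000
    level: float = 0.95
    seed: int | None = None

    def __post_init__(self):
        if self.method not in ("bootstrap", "jackknife"):
            raise ValueError(f"unknown resampling method {self.method!r}")
        if self.method == "bootstrap":
            if self.replicates < 100:
                raise ValueError("bootstrap needs at least 100 replicates")
            if self.seed is None:
                raise ValueError("bootstrap requires an explicit seed")
        if not 0.5 < self.level < 1.0:
            raise ValueError("confidence level must be in (0.5, 1)")


def _clip_bounds(name: str, lo: float, hi: float) -> tuple[float, float]:
    a, b = MEASURE_RANGES[name]
    return float(np.clip(lo, a, b)), float(np.clip(hi, a, b))


def _bootstrap_table_measure(name: str, counts: np.ndarray, n: int,
                             plan: ResamplingPlan) -> np.ndarray:
    rng = np.random.default_rng(plan.seed)
    probs = (counts / n).ravel()
    m = counts.shape[0]
    reps = rng.multinomial(n, probs, size=plan.replicates).reshape(-1, m, m)
    return measure_from_counts(name, reps)


def _bootstrap_pairs_measure(name: str, pairs: PairedAssessments,
                             plan: ResamplingPlan) -> np.ndarray:
    # index resampling; needed only for r_s where replicates may be degenerate.
    # Canonical sort keeps the interval invariant to input subject order.
    rng = np.random.default_rng(plan.seed)
    n = len(pairs)
    order = np.lexsort((pairs.b, pairs.a))
    pa, pb = pairs.a[order], pairs.b[order]
    out = np.empty(plan.replicates)
    for r in range(plan.replicates):
        idx = rng.integers(0, n, size=n)
        a, b = pa[idx], pb[idx]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            out[r] = np.nan
        else:
            out[r] = stats.spearmanr(a, b).statistic
    return out


def resample_ci(pairs: PairedAssessments, measure: str,
                plan: ResamplingPlan) -> MeasureValue:
    """Point estimate plus resampled confidence bounds for one measure.

    Deterministic given (data, plan, seed); invariant to subject order.
    Bounds are clipped to the measure's admissible range.  Raises if the
    measure is undefined on more than half of the replicates.
    """
    if len(pairs) < 2:
        raise ValueError("resampling needs at least 2 subjects")
    point = measure_from_pairs(measure, pairs)

    if plan.method == "jackknife":
        lo, hi = _jackknife_interval(pairs, measure, plan.level, point.estimate)
    else:
        if measure == "r_s":
            values = _bootstrap_pairs_measure(measure, pairs, plan)
        else:
            table = contingency_from_pairs(pairs)
            values = _bootstrap_table_measure(
                measure, table.counts.astype(float), table.n, plan)
        bad = ~np.isfinite(values)
        if bad.mean() > 0.5:
            raise ValueError(
                f"{measure} undefined on {bad.mean():.0%} of bootstrap "
                "replicates; data too degenerate for a resampled interval")
        values = values[~bad]
        alpha = 1.0 - plan.level
        lo, hi = np.quantile(values, [alpha / 2, 1 - alpha / 2])

    lo, hi = _clip_bounds(measure, lo, hi)
    # the percentile interval can exclude the point estimate only through
    # float fuzz on degenerate data; widen minimally so it always contains it
    lo = min(lo, point.estimate)
    hi = max(hi, point.estimate)
    return MeasureValue(measure, point.estimate, lo, hi)


def _jackknife_interval(pairs: PairedAssessments, measure: str, level: float,
                        theta_hat: float) -> tuple[float, float]:
    n = len(pairs)
    counts = contingency_from_pairs(pairs).counts.astype(float)
    occupied = np.argwhere(counts > 0)
    loo = np.repeat(counts[None, :, :], len(occupied), axis=0)
    for k, (i, j) in enumerate(occupied):
        loo[k, i, j] -= 1
    if measure == "r_s":
        thetas = np.empty(len(occupied))
        for k in range(len(occupied)):
            p = _counts_to_pairs(loo[k], pairs)
            try:
                thetas[k] = measure_from_pairs("r_s", p).estimate
            except ValueError:
                thetas[k] = np.nan
        if np.isnan(thetas).any():
            raise ValueError("r_s undefined on leave-one-out replicates")
    else:
        thetas = measure_from_counts(measure, loo)
    weights = counts[occupied[:, 0], occupied[:, 1]]
    pseudo = n * theta_hat - (n - 1) * thetas
    mean = np.average(pseudo, weights=weights)
    var = np.average((pseudo - mean) ** 2, weights=weights) * n / (n - 1)
    se = np.sqrt(var / n)
    z = stats.norm.ppf(0.5 + level / 2)
    return mean - z * se, mean + z * se


def _counts_to_pairs(counts: np.ndarray, template: PairedAssessments) -> PairedAssessments:
    i, j = np.nonzero(counts)
    reps = counts[i, j].astype(int)
    a = np.repeat(i + 1, reps)
    b = np.repeat(j + 1, reps)
    return PairedAssessments(tuple(range(len(a))), a, b, template.scale)


def significant_shift(value: MeasureValue) -> bool:
    """True iff the interval strictly excludes 0 (endpoint at 0 is not)."""
    if not value.has_bounds:
        raise ValueError("significance flag requires confidence bounds")
    return value.lower > 0.0 or value.upper < 0.0
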