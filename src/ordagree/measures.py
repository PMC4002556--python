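"""Agreement/disagreement measures for paired ordinal assessments.

The suite separates two sources of observed disagreement:

* systematic (group-level) disagreement — the relative position ``RP``, a
  difference of marginal shift probabilities, positive when the second
  assessment source uses higher categories;
* individual (subject-level) variability — the relative rank variance
  ``RV`` built from augmented mean ranks, and the disorder measure ``D``,
  the proportion of discordantly ordered subject pairs.

Plain percentage agreement ``PA`` and the Spearman rank correlation
``r_s`` complete the suite.  All internal kernels accept a stacked array
of tables ``(..., m, m)`` so resampling code can evaluate thousands of
replicate tables in one call.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats

from .core import ContingencyTable, PairedAssessments, contingency_from_pairs

__all__ = [
    "MeasureValue",
    "AugmentedRanks",
    "MEASURE_RANGES",
    "percentage_agreement",
    "relative_position",
    "augmented_mean_ranks",
    "relative_rank_variance",
    "disorder_measure",
    "spearman_rho",
]

#: Admissible range of each measure's point estimate.  RV's upper limit is
#: asymptotic; tiny-n pathological tables can exceed 1 and are reported
#: unclipped.
MEASURE_RANGES = {
    "PA": (0.0, 1.0),
    "RP": (-1.0, 1.0),
    "RV": (0.0, np.inf),
    "D": (0.0, 1.0),
    "r_s": (-1.0, 1.0),
}


@dataclass(frozen=True)
class MeasureValue:
    """A named measure with its point estimate and optional 95% bounds."""

    name: str
    estimate: float
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self):
        if self.name not in MEASURE_RANGES:
            raise ValueError(f"unknown measure name {self.name!r}")
        lo, hi = MEASURE_RANGES[self.name]
        # tolerate float fuzz at the admissible boundary
        if not (lo - 1e-9 <= self.estimate) or (
                self.name != "RV" and self.estimate > hi + 1e-9):
            raise ValueError(
                f"{self.name} estimate {self.estimate} outside [{lo}, {hi}]")
        if (self.lower is None) != (self.upper is None):
            raise ValueError("both or neither bound must be given")
        if self.lower is not None and self.lower > self.upper + 1e-12:
            raise ValueError("lower bound exceeds upper bound")

    @property
    def has_bounds(self) -> bool:
        return self.lower is not None


@dataclass(frozen=True)
class AugmentedRanks:
    """Per-cell mean augmented ranks of the two assessment orderings.

    ``rx[i, j]`` is the mean rank of subjects in cell ``(i, j)`` when
    subjects are ordered primarily by their first-assessment category with
    ties broken by the second; ``ry`` is the symmetric construction.
    """

    rx: np.ndarray
    ry: np.ndarray


def _as_counts(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.counts.astype(float)
    return np.asarray(table, dtype=float)


# ---------------------------------------------------------------------------
# batched kernels: counts has shape (..., m, m)

def _pa(counts: np.ndarray) -> np.ndarray:
    n = counts.sum(axis=(-2, -1))
    diag = np.diagonal(counts, axis1=-2, axis2=-1).sum(axis=-1)
    return diag / n


def _rp(counts: np.ndarray) -> np.ndarray:
    n = counts.sum(axis=(-2, -1), keepdims=True)
    p = counts.sum(axis=-1) / n[..., 0]          # first-source marginal
    q = counts.sum(axis=-2) / n[..., 0]          # second-source marginal
    Fp = np.cumsum(p, axis=-1)
    Fq = np.cumsum(q, axis=-1)
    Fp_prev = np.concatenate([np.zeros_like(Fp[..., :1]), Fp[..., :-1]], axis=-1)
    Fq_prev = np.concatenate([np.zeros_like(Fq[..., :1]), Fq[..., :-1]], axis=-1)
    p_a_lt_b = (q * Fp_prev).sum(axis=-1)
    p_b_lt_a = (p * Fq_prev).sum(axis=-1)
    return p_a_lt_b - p_b_lt_a


def _aug_ranks(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    row_tot = counts.sum(axis=-1)
    col_tot = counts.sum(axis=-2)
    rows_before = np.cumsum(row_tot, axis=-1) - row_tot      # sum_{k<i} n_k.
    cols_before = np.cumsum(col_tot, axis=-1) - col_tot      # sum_{l<j} n_.l
    left_in_row = np.cumsum(counts, axis=-1) - counts        # sum_{l<j} n_il
    above_in_col = np.cumsum(counts, axis=-2) - counts       # sum_{k<i} n_kj
    half = (counts + 1.0) / 2.0
    rx = rows_before[..., :, None] + left_in_row + half
    ry = cols_before[..., None, :] + above_in_col + half
    return rx, ry


def _rv(counts: np.ndarray) -> np.ndarray:
    n = counts.sum(axis=(-2, -1))
    rx, ry = _aug_ranks(counts)
    ss = (counts * (rx - ry) ** 2).sum(axis=(-2, -1))
    return 6.0 * ss / n**3


def _disorder(counts: np.ndarray) -> np.ndarray:
    """Discordant subject-pair proportion out of all C(n, 2) pairs."""
    n = counts.sum(axis=(-2, -1))
    # for each cell (i, j): number of subjects in cells with larger first
    # category and strictly smaller second category
    below_right = np.cumsum(counts[..., ::-1, :], axis=-2)[..., ::-1, :] - counts
    strictly_left = np.cumsum(below_right, axis=-1) - below_right
    disordered = (counts * strictly_left).sum(axis=(-2, -1))
    return disordered / (n * (n - 1) / 2.0)


_KERNELS = {"PA": _pa, "RP": _rp, "RV": _rv, "D": _disorder}


# ---------------------------------------------------------------------------
# public measure API

def percentage_agreement(table: ContingencyTable) -> MeasureValue:
    """Proportion of pairs on the agreement diagonal."""
    return MeasureValue("PA", float(_pa(_as_counts(table))))


def relative_position(table: ContingencyTable) -> MeasureValue:
    """Systematic marginal shift: P(A < B) − P(B < A).

    The shift probabilities are evaluated from the two marginal
    distributions over all n² cross-combinations (self-pairings included).
    Positive values mean the second assessment source occupies higher
    categories.
    """
    return MeasureValue("RP", float(_rp(_as_counts(table))))


def augmented_mean_ranks(table: ContingencyTable) -> AugmentedRanks:
    """Cell-wise mean ranks under the two tie-broken subject orderings.

    ``rx_ij = Σ_{k<i} n_k· + Σ_{l<j} n_il + (n_ij + 1)/2`` and symmetrically
    for ``ry``; each weighted rank matrix sums to ``n(n+1)/2``.
    """
    rx, ry = _aug_ranks(_as_counts(table))
    return AugmentedRanks(rx=rx, ry=ry)


def relative_rank_variance(table: ContingencyTable) -> MeasureValue:
    """Rank-based variance of individual disagreement.

    ``RV = (6/n³) Σ_ij n_ij (rx_ij − ry_ij)²`` over the augmented mean
    ranks; zero when every subject's two ranks coincide.  Values are
    reported unclipped: the [0, 1] range is an asymptotic statement and
    tiny-n reversal tables can exceed it.
    """
    return MeasureValue("RV", float(_rv(_as_counts(table))))


def disorder_measure(data) -> MeasureValue:
    """Proportion of subject pairs whose two assessments are discordant.

    A pair of subjects {k, l} is disordered when
    ``(a_k − a_l)(b_k − b_l) < 0``; pairs tied on either coordinate count in
    the C(n, 2) denominator but never as disordered.  Accepts either a
    :class:`PairedAssessments` collection or a :class:`ContingencyTable`
    (the two routes are algebraically identical).
    """
    if isinstance(data, PairedAssessments):
        if len(data) < 2:
            raise ValueError("D undefined for fewer than 2 subjects")
        counts = _as_counts(contingency_from_pairs(data))
    else:
        counts = _as_counts(data)
        if counts.sum() < 2:
            raise ValueError("D undefined for fewer than 2 subjects")
    return MeasureValue("D", float(_disorder(counts)))


def spearman_rho(pairs: PairedAssessments) -> MeasureValue:
    """Spearman rank correlation of the two assessments (mid-ranks for ties)."""
    if len(pairs) < 2:
        raise ValueError("r_s undefined for fewer than 2 subjects")
    if np.ptp(pairs.a) == 0 or np.ptp(pairs.b) == 0:
        raise ValueError("zero rank variance: constant assessment column")
    rho = stats.spearmanr(pairs.a, pairs.b).statistic
    return MeasureValue("r_s", float(rho))


def measure_from_counts(name: str, counts: np.ndarray) -> np.ndarray:
    """Evaluate a table-based measure kernel on stacked counts ``(..., m, m)``.

    Used by the resampling layer; ``r_s`` is not table-batched here.
    """
    try:
        return _KERNELS[name](np.asarray(counts, dtype=float))
    except KeyError:
        raise ValueError(f"no batched kernel for measure {name!r}") from None


def measure_from_pairs(name: str, pairs: PairedAssessments) -> MeasureValue:
    """Dispatch any of the five measures by name from raw pairs."""
    if name == "r_s":
        return spearman_rho(pairs)
    if name == "D":
        return disorder_measure(pairs)
    table = contingency_from_pairs(pairs)
    return {
        "PA": percentage_agreement,
        "RP": relative_position,
        "RV": relative_rank_variance,
    }[name](table)
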