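"""Core data structures for paired ordinal rating-scale data.

Categories are coded ``1..m`` internally; the label/code mapping lives only
in :class:`ResponseScale`.  All downstream measures are rank-invariant, so
only the order of the codes matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ResponseScale",
    "PairedAssessments",
    "ContingencyTable",
    "MarginalDistribution",
    "OrdinalSummary",
    "contingency_from_pairs",
    "marginals",
    "ordinal_summary",
    "DEFAULT_SCALE",
]


@dataclass(frozen=True)
class ResponseScale:
    """An ordered categorical response scale with codes ``1..m``.

    Parameters
    ----------
    labels
        Category names in increasing order of severity.  Must be distinct
        and at least two.
    """

    labels: tuple[str, ...]

    def __init__(self, labels: Iterable[str]):
        labels = tuple(str(l) for l in labels)
        if len(labels) < 2:
            raise ValueError("a response scale needs at least 2 categories")
        if len(set(labels)) != len(labels):
            raise ValueError("scale labels must be distinct")
        object.__setattr__(self, "labels", labels)

    @property
    def m(self) -> int:
        """Number of categories."""
        return len(self.labels)

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(range(1, self.m + 1))

    def code_of(self, value) -> int:
        """Map a label or an integer code to a validated code in ``1..m``."""
        if isinstance(value, str):
            stripped = value.strip()
            try:
                return self.labels.index(stripped) + 1
            except ValueError:
                # fall through: numeric string like "3"
                try:
                    value = int(stripped)
                except ValueError:
                    raise ValueError(f"unknown scale label {value!r}") from None
        code = int(value)
        if not 1 <= code <= self.m:
            raise ValueError(f"code {code} outside 1..{self.m}")
        return code

    def label_of(self, code: int) -> str:
        return self.labels[int(code) - 1]


#: The five-point problem scale used as the package default.
DEFAULT_SCALE = ResponseScale(("no", "slight", "moderate", "major", "total"))


@dataclass(frozen=True)
class PairedAssessments:
    """A collection of complete paired assessments of one item.

    Each subject carries two category codes on the same scale: ``a`` for the
    first assessment source and ``b`` for the second.  Subjects with a
    missing response on either side must be excluded before construction
    (pairwise-complete deletion), so every stored pair is complete.
    """

    subject_ids: tuple
    a: np.ndarray
    b: np.ndarray
    scale: ResponseScale = field(default=DEFAULT_SCALE)

    def __init__(self, subject_ids: Sequence, a, b, scale: ResponseScale = DEFAULT_SCALE):
        subject_ids = tuple(subject_ids)
        a = np.asarray(a, dtype=np.int64)
        b = np.asarray(b, dtype=np.int64)
        if not (len(subject_ids) == a.shape[0] == b.shape[0]):
            raise ValueError("subject_ids, a and b must have equal length")
        if a.ndim != 1:
            raise ValueError("a and b must be 1-dimensional")
        for name, arr in (("a", a), ("b", b)):
            bad = (arr < 1) | (arr > scale.m)
            if bad.any():
                k = int(np.argmax(bad))
                raise ValueError(
                    f"subject {subject_ids[k]!r}: response {name}={arr[k]} "
                    f"outside 1..{scale.m}"
                )
        a.setflags(write=False)
        b.setflags(write=False)
        object.__setattr__(self, "subject_ids", subject_ids)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "scale", scale)

    def __len__(self) -> int:
        return len(self.subject_ids)

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    def swapped(self) -> "PairedAssessments":
        """The same subjects with the two assessment sources interchanged."""
        return PairedAssessments(self.subject_ids, self.b, self.a, self.scale)

    @classmethod
    def from_tuples(cls, pairs: Iterable[tuple[int, int]],
                    scale: ResponseScale = DEFAULT_SCALE) -> "PairedAssessments":
        pairs = list(pairs)
        ids = tuple(range(1, len(pairs) + 1))
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        return cls(ids, a, b, scale)


@dataclass(frozen=True)
class ContingencyTable:
    """Square table of pair counts ``n_ij``.

    Rows index the first assessment's category ``i``, columns the second
    assessment's category ``j`` (storage orientation; display orientation is
    handled by the reporting layer).
    """

    counts: np.ndarray

    def __init__(self, counts):
        counts = np.asarray(counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.array_equal(rounded, counts):
                raise ValueError("counts must be integers")
            counts = rounded.astype(np.int64)
        counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.sum() < 1:
            raise ValueError("table must contain at least one pair")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @property
    def m(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.counts.T.copy())

    def to_pairs(self, scale: ResponseScale | None = None) -> PairedAssessments:
        """Expand the table back into one pair per counted subject."""
        if scale is None:
            scale = DEFAULT_SCALE if self.m == DEFAULT_SCALE.m else ResponseScale(
                tuple(f"c{k}" for k in range(1, self.m + 1)))
        i, j = np.nonzero(self.counts)
        reps = self.counts[i, j]
        a = np.repeat(i + 1, reps)
        b = np.repeat(j + 1, reps)
        return PairedAssessments(tuple(range(1, len(a) + 1)), a, b, scale)


@dataclass(frozen=True)
class MarginalDistribution:
    """Proportions over the ``m`` categories of one assessment source."""

    proportions: np.ndarray

    def __init__(self, proportions):
        p = np.asarray(proportions, dtype=float)
        if p.ndim != 1 or p.shape[0] < 2:
            raise ValueError("proportions must be a 1-d vector of length >= 2")
        if (p < -1e-12).any():
            raise ValueError("proportions must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        p = np.clip(p, 0.0, None)
        p.setflags(write=False)
        object.__setattr__(self, "proportions", p)

    @property
    def m(self) -> int:
        return self.proportions.shape[0]

    @property
    def cumulative(self) -> np.ndarray:
        F = np.cumsum(self.proportions)
        F[-1] = 1.0
        return F


@dataclass(frozen=True)
class OrdinalSummary:
    """Median and quartile categories of an ordinal distribution."""

    median: int
    q1: int
    q3: int

    def __post_init__(self):
        if not self.q1 <= self.median <= self.q3:
            raise ValueError("requires q1 <= median <= q3")

    def format(self, scale: ResponseScale | None = None) -> str:
        if scale is None:
            return f"Md {self.median} (Q1 {self.q1}; Q3 {self.q3})"
        return (f"Md {scale.label_of(self.median)} "
                f"(Q1 {scale.label_of(self.q1)}; Q3 {scale.label_of(self.q3)})")


def contingency_from_pairs(pairs: PairedAssessments,
                           scale: ResponseScale | None = None) -> ContingencyTable:
    """Count pairs into an ``m`` × ``m`` contingency table.

    ``n_ij`` is the number of subjects with first response ``i`` and second
    response ``j``; the total equals the number of pairs.
    """
    if scale is None:
        scale = pairs.scale
    if len(pairs) == 0:
        raise ValueError("no complete pairs")
    m = scale.m
    flat = (pairs.a - 1) * m + (pairs.b - 1)
    counts = np.bincount(flat, minlength=m * m).reshape(m, m)
    return ContingencyTable(counts)


def marginals(table: ContingencyTable) -> tuple[MarginalDistribution, MarginalDistribution]:
    """Row (first assessment) and column (second assessment) marginals."""
    n = table.n
    first = MarginalDistribution(table.counts.sum(axis=1) / n)
    second = MarginalDistribution(table.counts.sum(axis=0) / n)
    return first, second


def ordinal_summary(marginal: MarginalDistribution,
                    scale: ResponseScale | None = None) -> OrdinalSummary:
    """Median and quartile categories of a marginal distribution.

    Convention: for each target proportion p in {0.25, 0.5, 0.75} the
    reported category is the smallest category whose cumulative proportion
    is >= p.  This is a documented package convention for ordinal data, not
    a universal rule.
    """
    if scale is not None and scale.m != marginal.m:
        raise ValueError("scale and marginal disagree on number of categories")
    F = marginal.cumulative
    q1, md, q3 = (int(np.searchsorted(F, p) + 1) for p in (0.25, 0.5, 0.75))
    return OrdinalSummary(median=md, q1=q1, q3=q3)
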