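"""Synthetic paired ordinal assessments from a latent-trait threshold model.

Each subject carries a standard-normal latent severity; each assessment
source observes it with its own additive bias (producing systematic
disagreement, i.e. a nonzero RP) and its own normal noise (producing
individual variability, i.e. RV and D), then cuts the observed value into
ordered categories at source-specific thresholds.  A study-level generator
adds per-item difficulty offsets, a pool of observers with personal biases,
and item-wise missingness, emulating multi-item paired-assessment studies.

The distributional choices (normal trait, normal noise, fixed thresholds)
are the generator's own modelling assumptions, intended for testing and
power exploration rather than for fitting real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DEFAULT_SCALE, PairedAssessments, ResponseScale

__all__ = [
    "RaterModel",
    "StudyDesign",
    "DEFAULT_THRESHOLDS",
    "generate_paired_assessments",
    "generate_study",
]

#: Equally spaced cuts giving non-degenerate occupancy of all five
#: categories under a standard-normal trait.
DEFAULT_THRESHOLDS = (-1.5, -0.5, 0.5, 1.5)


@dataclass(frozen=True)
class RaterModel:
    """One assessment source on the latent scale.

    bias
        Additive shift applied to the latent trait before categorisation;
        differences in bias between the two sources create systematic
        disagreement.
    noise
        Standard deviation of the source's own observation noise; drives
        individual variability.
    thresholds
        Strictly increasing cut points defining m = len(thresholds) + 1
        ordered categories.
    """

    bias: float = 0.0
    noise: float = 0.3
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS

    def __post_init__(self):
        t = tuple(float(x) for x in self.thresholds)
        if len(t) < 1 or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if self.noise < 0:
            raise ValueError("noise SD must be non-negative")
        object.__setattr__(self, "thresholds", t)

    @property
    def m(self) -> int:
        return len(self.thresholds) + 1

    def categorize(self, latent: np.ndarray, noise_draws: np.ndarray) -> np.ndarray:
        observed = latent + self.bias + self.noise * noise_draws
        return np.searchsorted(np.asarray(self.thresholds), observed) + 1


@dataclass(frozen=True)
class StudyDesign:
    """Shape of a simulated multi-item paired-assessment study."""

    n_subjects: int
    items: tuple[str, ...] = ("item_1",)
    item_offsets: tuple[float, ...] | None = None
    n_observers: int = 0
    observer_bias_sd: float = 0.0
    completion_prob: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        items = tuple(str(i) for i in self.items)
        if len(items) == 0 or len(set(items)) != len(items):
            raise ValueError("items must be non-empty and distinct")
        offsets = self.item_offsets
        if offsets is None:
            offsets = (0.0,) * len(items)
        offsets = tuple(float(x) for x in offsets)
        if len(offsets) != len(items):
            raise ValueError("item_offsets must match items")
        if not 0.0 < self.completion_prob <= 1.0:
            raise ValueError("completion probability must be in (0, 1]")
        if self.observer_bias_sd < 0:
            raise ValueError("observer bias SD must be non-negative")
        if self.observer_bias_sd > 0 and self.n_observers < 1:
            raise ValueError("observer heterogeneity needs n_observers >= 1")
        object.__setattr__(self, "items", items)
        object.__setattr__(self, "item_offsets", offsets)


def _scale_for(model: RaterModel) -> ResponseScale:
    if model.m == DEFAULT_SCALE.m:
        return DEFAULT_SCALE
    return ResponseScale(tuple(f"c{k}" for k in range(1, model.m + 1)))


def _check_models(model_a: RaterModel, model_b: RaterModel):
    if model_a.m != model_b.m:
        raise ValueError("both rater models must define the same number of categories")


def generate_paired_assessments(model_a: RaterModel, model_b: RaterModel,
                                n: int, seed: int) -> PairedAssessments:
    """Draw n complete pairs from the two-source latent-trait model.

    Per subject k: latent trait θ_k ~ N(0, 1); source s observes
    θ_k + bias_s + noise_s·ε with ε ~ N(0, 1) and categorises at its own
    thresholds.  Deterministic given the seed.
    """
    _check_models(model_a, model_b)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    ss_theta, ss_a, ss_b = np.random.SeedSequence(seed).spawn(3)
    theta = np.random.default_rng(ss_theta).standard_normal(n)
    a = model_a.categorize(theta, np.random.default_rng(ss_a).standard_normal(n))
    b = model_b.categorize(theta, np.random.default_rng(ss_b).standard_normal(n))
    ids = tuple(f"s{k:04d}" for k in range(1, n + 1))
    return PairedAssessments(ids, a, b, _scale_for(model_a))


def generate_study(design: StudyDesign, model_a: RaterModel,
                   model_b: RaterModel) -> pd.DataFrame:
    """Simulate a long-format study table, one record per (subject, item).

    Columns: subject_id, item_id, response_a, response_b (nullable integer;
    NA where the record is incomplete).  Each subject is examined by exactly
    one observer; an observer's personal bias is drawn from
    N(model_b.bias, observer_bias_sd²) and replaces model_b's bias for all
    of that observer's subjects.  Item offsets shift the latent trait per
    item.  Missingness strikes each (subject, item, side) response
    independently with probability 1 − completion_prob.

    The seed drives a hierarchical stream (traits, observers, then one
    child per item) so that changing one design field does not reshuffle
    unrelated draws; with observer_bias_sd = 0 the output is exactly the
    no-observer study.
    """
    _check_models(model_a, model_b)
    root = np.random.SeedSequence(design.seed)
    ss_theta, ss_obs, ss_items = root.spawn(3)
    n = design.n_subjects
    theta = np.random.default_rng(ss_theta).standard_normal(n)

    rng_obs = np.random.default_rng(ss_obs)
    if design.n_observers > 0:
        assignment = rng_obs.integers(0, design.n_observers, size=n)
        observer_z = rng_obs.standard_normal(design.n_observers)
    else:
        assignment = np.zeros(n, dtype=int)
        observer_z = np.zeros(1)
    # exactly zero effect when the heterogeneity SD is zero
    b_bias = model_b.bias + design.observer_bias_sd * observer_z[assignment]

    ids = [f"s{k:04d}" for k in range(1, n + 1)]
    records = []
    item_streams = ss_items.spawn(len(design.items))
    ta = np.asarray(model_a.thresholds)
    tb = np.asarray(model_b.thresholds)
    for item, offset, ss in zip(design.items, design.item_offsets, item_streams):
        rng = np.random.default_rng(ss)
        shifted = theta + offset
        obs_a = shifted + model_a.bias + model_a.noise * rng.standard_normal(n)
        obs_b = shifted + b_bias + model_b.noise * rng.standard_normal(n)
        a = np.searchsorted(ta, obs_a) + 1.0
        b = np.searchsorted(tb, obs_b) + 1.0
        if design.completion_prob < 1.0:
            a[rng.random(n) > design.completion_prob] = np.nan
            b[rng.random(n) > design.completion_prob] = np.nan
        for k in range(n):
            records.append((ids[k], item, a[k], b[k]))

    df = pd.DataFrame(records,
                      columns=["subject_id", "item_id", "response_a", "response_b"])
    df["response_a"] = df["response_a"].astype("Int64")
    df["response_b"] = df["response_b"].astype("Int64")
    return df
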