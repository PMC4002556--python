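"""End-to-end study analysis: read paired assessments, compute the measure
bundle per item with confidence intervals, summarise across items, and
render report tables and contingency-table grids.

Input format: CSV with header ``subject_id,item_id,response_a,response_b``;
responses are integer codes 1..m or exact scale labels; blank/NA means
missing.  A record missing either response is retained for accounting but
excluded from that item's analysis (pairwise-complete deletion), so n
varies by item.
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_SCALE,
    ContingencyTable,
    PairedAssessments,
    ResponseScale,
    contingency_from_pairs,
)
from .inference import ResamplingPlan, resample_ci, significant_shift
from .measures import MeasureValue, disorder_measure, percentage_agreement, spearman_rho

__all__ = [
    "ItemResult",
    "SkippedItem",
    "StudySummary",
    "read_study_csv",
    "item_pairs",
    "analyze_item",
    "analyze_study",
    "render_contingency",
    "write_results",
]

_NA_TOKENS = {"", "na", "n/a", "nan", "none", "."}


@dataclass(frozen=True)
class ItemResult:
    """The measure bundle for one item — one row of a study report table."""

    item_id: str
    n: int
    pa: MeasureValue
    rp: MeasureValue
    rv: MeasureValue
    d: MeasureValue
    r_s: MeasureValue | None = None

    @property
    def rp_significant(self) -> bool:
        return significant_shift(self.rp)


@dataclass(frozen=True)
class SkippedItem:
    item_id: str
    n: int
    reason: str


@dataclass(frozen=True)
class StudySummary:
    """Cross-item median and range for each measure."""

    medians: dict
    ranges: dict
    n_items: int

    @classmethod
    def from_results(cls, results: list[ItemResult]) -> "StudySummary":
        values = {
            "PA": [r.pa.estimate for r in results],
            "RP": [r.rp.estimate for r in results],
            "RV": [r.rv.estimate for r in results],
            "D": [r.d.estimate for r in results],
        }
        rs = [r.r_s.estimate for r in results if r.r_s is not None]
        if rs:
            values["r_s"] = rs
        medians = {k: float(np.median(v)) for k, v in values.items()}
        ranges = {k: (float(min(v)), float(max(v))) for k, v in values.items()}
        return cls(medians=medians, ranges=ranges, n_items=len(results))


def read_study_csv(path, scale: ResponseScale = DEFAULT_SCALE) -> pd.DataFrame:
    """Parse a long-format study CSV into coded records.

    Returns a frame with columns subject_id, item_id, response_a,
    response_b; responses are nullable Int64 codes in 1..m.  Unknown labels
    or out-of-range codes raise with the offending row number; duplicate
    (subject, item) records raise.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["subject_id", "item_id", "response_a", "response_b"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"study CSV missing column(s): {', '.join(missing)}")

    def decode(col: str) -> pd.Series:
        out = []
        for row, raw in enumerate(df[col], start=2):  # row 1 is the header
            token = raw.strip()
            if token.lower() in _NA_TOKENS:
                out.append(pd.NA)
                continue
            try:
                out.append(scale.code_of(token))
            except ValueError as exc:
                raise ValueError(f"row {row}, column {col}: {exc}") from None
        return pd.Series(out, dtype="Int64")

    coded = df[["subject_id", "item_id"]].copy()
    coded["response_a"] = decode("response_a")
    coded["response_b"] = decode("response_b")

    dup = coded.duplicated(subset=["subject_id", "item_id"])
    if dup.any():
        sid, iid = coded.loc[dup.idxmax(), ["subject_id", "item_id"]]
        raise ValueError(f"duplicate record for subject {sid!r}, item {iid!r}")
    return coded


def item_pairs(study: pd.DataFrame, item_id: str,
               scale: ResponseScale = DEFAULT_SCALE) -> PairedAssessments:
    """Complete pairs for one item (incomplete records dropped)."""
    sub = study[study["item_id"] == item_id]
    complete = sub.dropna(subset=["response_a", "response_b"])
    if len(complete) == 0:
        raise ValueError(f"item {item_id!r}: no complete pairs")
    return PairedAssessments(
        tuple(complete["subject_id"]),
        complete["response_a"].to_numpy(dtype=np.int64),
        complete["response_b"].to_numpy(dtype=np.int64),
        scale,
    )


def analyze_item(pairs: PairedAssessments, plan: ResamplingPlan,
                 orientation: str = "ab", spearman: bool = True) -> ItemResult:
    """Compute the full measure bundle for one item.

    orientation
        ``"ab"``: positive RP means the b-source (second column) uses higher
        categories; ``"ba"`` flips the roles so positive RP means the
        a-source is higher.  Only RP's sign is affected.
    """
    if orientation not in ("ab", "ba"):
        raise ValueError("orientation must be 'ab' or 'ba'")
    if len(pairs) < 2:
        raise ValueError("analysis needs at least 2 complete pairs")
    oriented = pairs if orientation == "ab" else pairs.swapped()
    table = contingency_from_pairs(pairs)
    rp = resample_ci(oriented, "RP", plan)
    rv = resample_ci(pairs, "RV", plan)
    r_s = spearman_rho(pairs) if spearman else None
    return ItemResult(
        item_id="",
        n=len(pairs),
        pa=percentage_agreement(table),
        rp=rp,
        rv=rv,
        d=disorder_measure(pairs),
        r_s=r_s,
    )


def analyze_study(study: pd.DataFrame, plan: ResamplingPlan,
                  orientation: str = "ab", spearman: bool = True,
                  scale: ResponseScale = DEFAULT_SCALE,
                  ) -> tuple[list[ItemResult], list[SkippedItem], StudySummary]:
    """Per-item measure bundles plus a cross-item summary.

    Items whose data are degenerate (fewer than 2 complete pairs, or a
    constant column when r_s is requested) become structured skip records
    instead of aborting the study.  Bootstrap seeds are derived per item
    from the plan seed so results do not depend on item order.
    """
    items = list(dict.fromkeys(study["item_id"]))
    results: list[ItemResult] = []
    skipped: list[SkippedItem] = []
    for item in items:
        sub = study[study["item_id"] == item]
        complete = sub.dropna(subset=["response_a", "response_b"])
        n = len(complete)
        try:
            pairs = item_pairs(study, item, scale)
            item_plan = plan
            if plan.method == "bootstrap":
                child = np.random.SeedSequence(
                    entropy=plan.seed,
                    spawn_key=(zlib.crc32(str(item).encode("utf-8")),))
                item_plan = ResamplingPlan(plan.method, plan.replicates,
                                           plan.level, child.generate_state(1)[0])
            res = analyze_item(pairs, item_plan, orientation, spearman)
            results.append(ItemResult(item, res.n, res.pa, res.rp, res.rv,
                                      res.d, res.r_s))
        except ValueError as exc:
            skipped.append(SkippedItem(item, n, str(exc)))
    if not results:
        raise ValueError("no analyzable items in study")
    return results, skipped, StudySummary.from_results(results)


def render_contingency(table: ContingencyTable,
                       scale: ResponseScale | None = None,
                       mark: str = "*") -> str:
    """Plain-text grid of the pair counts with marginal totals.

    Display orientation: first assessment's categories ascend left to
    right, second assessment's ascend bottom to top, so the agreement
    diagonal runs from the lower-left to the upper-right corner; its cells
    are marked.
    """
    m = table.m
    if scale is not None and scale.m != m:
        raise ValueError("scale does not match table size")
    labels = (scale.labels if scale is not None
              else tuple(str(k) for k in range(1, m + 1)))
    counts = table.counts
    col_marg = counts.sum(axis=1)  # per first-assessment category
    row_marg = counts.sum(axis=0)  # per second-assessment category

    head = [""] + list(labels) + ["total"]
    rows = [head]
    for j in range(m - 1, -1, -1):  # second assessment, top = highest
        cells = []
        for i in range(m):
            c = str(counts[i, j])
            cells.append(c + mark if i == j else c)
        rows.append([labels[j]] + cells + [str(row_marg[j])])
    rows.append(["total"] + [str(x) for x in col_marg] + [str(table.n)])

    widths = [max(len(r[k]) for r in rows) for k in range(len(head))]
    lines = ["  ".join(cell.rjust(w) for cell, w in zip(r, widths)) for r in rows]
    return "\n".join(lines) + "\n"


def _fmt(x: float, decimals: int) -> str:
    return f"{x:.{decimals}f}"


def format_measure(value: MeasureValue, decimals: int = 2) -> str:
    """Render e.g. ``0.37 (0.27 to 0.46)`` in the report-table style."""
    s = _fmt(value.estimate, decimals)
    if value.has_bounds:
        s += f" ({_fmt(value.lower, decimals)} to {_fmt(value.upper, decimals)})"
    return s


def results_frame(results: list[ItemResult], decimals: int = 2) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "item_id": r.item_id,
            "n": r.n,
            "PA": f"{round(r.pa.estimate * 100):.0f}%",
            "RP": format_measure(r.rp, decimals),
            "RP_significant": r.rp_significant,
            "RV": format_measure(r.rv, decimals),
            "D": _fmt(r.d.estimate, decimals),
        }
        if r.r_s is not None:
            row["r_s"] = _fmt(r.r_s.estimate, decimals)
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(results: list[ItemResult], summary: StudySummary, path,
                  skipped: list[SkippedItem] = (), decimals: int = 2,
                  orientation: str = "ab", seed: int | None = None) -> None:
    """Write the per-item report CSV with a trailing summary block.

    PA is printed as a whole percentage; other measures to ``decimals``
    places with CIs as ``(lo to hi)``.  A header line states the RP sign
    convention; the footer logs per-item exclusions and the seed.
    """
    if not results:
        raise ValueError("no results to write")
    buf = io.StringIO()
    convention = ("positive RP = second source (b) uses higher categories"
                  if orientation == "ab" else
                  "positive RP = first source (a) uses higher categories")
    buf.write(f"# RP sign convention: {convention}\n")
    results_frame(results, decimals).to_csv(buf, index=False)
    buf.write("\n# summary (median and range across items)\n")
    for name, med in summary.medians.items():
        lo, hi = summary.ranges[name]
        if name == "PA":
            buf.write(f"# PA: median {round(med * 100):.0f}% "
                      f"(range {round(lo * 100):.0f}% to {round(hi * 100):.0f}%)\n")
        else:
            buf.write(f"# {name}: median {_fmt(med, decimals)} "
                      f"(range {_fmt(lo, decimals)} to {_fmt(hi, decimals)})\n")
    for s in skipped:
        buf.write(f"# skipped item {s.item_id}: n={s.n}: {s.reason}\n")
    if seed is not None:
        buf.write(f"# seed: {seed}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
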