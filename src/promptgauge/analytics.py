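"""Corpus-level evaluation of draft-message usage, editing, and sentiment.

Works on a flat sequence of :class:`MessageEvent` records — one per
AI-generated draft reply — each carrying the study period (pre-period with
the original prompt, post-period with the engineered prompt, and an optional
third phase), whether the provider saw and used the draft, an optional
thumbs-down negative-sentiment flag, and the draft/final text pair when the
draft was used.

Outputs mirror a pre-post quasi-experimental analysis: per-period usage and
negative-sentiment rates, the 4 x 2 edit-category-by-period contingency
table (unused drafts count as "different": a draft the provider discarded
and rewrote from scratch is maximally edited), the Pearson chi-square test
of independence, and unadjusted odds ratios with Wald confidence intervals.
Mixed-model (random-intercept) adjusted estimates are deliberately not
implemented: they require per-provider raw data and are a routine fit for
statsmodels/lme4 users.

All printed percentages flow through one rounding rule — half away from
zero to 1 decimal place, computed in exact integer arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .editdist import EditCategory, compare
from .errors import InputError

__all__ = [
    "PERIODS",
    "MessageEvent",
    "ContingencyTable",
    "SummaryReport",
    "round_pct",
    "summarize",
    "edit_category_table",
    "chi_square_independence",
    "odds_ratio_2x2",
    "sentiment_rates",
]

PERIODS = ("pre", "post", "phase3")

CATEGORY_ORDER = (
    EditCategory.IDENTICAL,
    EditCategory.NEARLY_IDENTICAL,
    EditCategory.SIMILAR,
    EditCategory.DIFFERENT,
)


@dataclass(frozen=True)
class MessageEvent:
    """One generated draft's lifecycle record."""

    message_id: str
    provider_id: str
    period: str
    seen: bool = True
    used: bool = False
    inquiry_class: str | None = None
    sentiment_negative: bool | None = None
    draft_text: str | None = None
    final_text: str | None = None

    def __post_init__(self) -> None:
        if self.period not in PERIODS:
            raise InputError(f"period must be one of {PERIODS}, got {self.period!r}")
        if self.inquiry_class is not None and self.inquiry_class not in (
            "general", "test_results", "medication", "paperwork"
        ):
            raise InputError(f"unknown inquiry_class {self.inquiry_class!r}")
        if self.used and not self.seen:
            raise InputError(f"event {self.message_id}: used implies seen")
        if self.sentiment_negative is not None and not self.seen:
            raise InputError(f"event {self.message_id}: sentiment implies seen")


@dataclass(frozen=True)
class ContingencyTable:
    """A labelled table of non-negative counts."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if len(set(self.row_labels)) != len(self.row_labels):
            raise InputError("row labels must be unique")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise InputError("column labels must be unique")
        arr = np.asarray(self.counts)
        if arr.shape != (len(self.row_labels), len(self.col_labels)):
            raise InputError("counts shape does not match labels")
        if (arr < 0).any():
            raise InputError("counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)

    @property
    def total(self) -> int:
        return int(self.as_array().sum())


def round_pct(num: int, den: int) -> float:
    """``100 * num / den`` rounded half-away-from-zero to 1 decimal place.

    Exact integer arithmetic — the single source of truth for every
    percentage the package prints (counts are non-negative, so half away
    from zero coincides with half up).
    """
    if den <= 0:
        raise InputError("denominator must be positive")
    if num < 0:
        raise InputError("count must be non-negative")
    tenths = (2000 * num + den) // (2 * den)
    return tenths / 10.0


# ---------------------------------------------------------------------------
# usage / sentiment summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SummaryReport:
    """Per-period and pooled usage/sentiment summary.

    ``rows`` maps a period name (or "pooled") to a dict with keys
    ``total``, ``seen``, ``used``, ``usage_pct``, ``sentiment_negative``
    (None when no flags present) and ``sentiment_pct``.
    """

    rows: Mapping[str, Mapping[str, object]]

    def __getitem__(self, period: str) -> Mapping[str, object]:
        return self.rows[period]


def _summary_row(events: Sequence[MessageEvent]) -> dict:
    total = len(events)
    seen = sum(e.seen for e in events)
    used = sum(e.used for e in events)
    has_sentiment = any(e.sentiment_negative is not None for e in events)
    neg = sum(bool(e.sentiment_negative) for e in events)
    return {
        "total": total,
        "seen": seen,
        "used": used,
        "usage_pct": round_pct(used, total),
        "sentiment_negative": neg if has_sentiment else None,
        "sentiment_pct": round_pct(neg, seen) if (has_sentiment and seen) else None,
    }


def summarize(events: Sequence[MessageEvent]) -> SummaryReport:
    """Exact per-period and pooled counts with 1-dp percentages.

    Usage percentage is used/total generated; sentiment percentage is
    negative/seen (a rating requires the provider to have seen the draft).
    """
    events = list(events)
    if not events:
        raise InputError("events must be non-empty")
    rows: dict[str, dict] = {}
    for period in PERIODS:
        sub = [e for e in events if e.period == period]
        if sub:
            rows[period] = _summary_row(sub)
    rows["pooled"] = _summary_row(events)
    return SummaryReport(rows=rows)


def sentiment_rates(events: Sequence[MessageEvent]) -> dict[str, tuple[int, float]]:
    """Per-period (negative count, percentage of seen messages)."""
    out: dict[str, tuple[int, float]] = {}
    for period in PERIODS:
        sub = [e for e in events if e.period == period and e.seen]
        if not sub or all(e.sentiment_negative is None for e in sub):
            continue
        neg = sum(bool(e.sentiment_negative) for e in sub)
        out[period] = (neg, round_pct(neg, len(sub)))
    return out


# ---------------------------------------------------------------------------
# edit-category contingency table
# ---------------------------------------------------------------------------

def edit_category_table(
    events: Sequence[MessageEvent],
    variant: str = "osa",
    periods: Sequence[str] = ("pre", "post"),
) -> ContingencyTable:
    """4 x len(periods) table of edit category by period over seen events.

    Used drafts are compared text-vs-text (both texts required — missing
    ones raise listing the offending message ids); drafts the provider never
    used land in "different" regardless of text availability, since a
    discarded draft is a fully edited one.  Column sums equal the per-period
    seen totals by construction.
    """
    counts = {p: {c: 0 for c in CATEGORY_ORDER} for p in periods}
    missing: list[str] = []
    for e in events:
        if not e.seen or e.period not in periods:
            continue
        if not e.used:
            counts[e.period][EditCategory.DIFFERENT] += 1
            continue
        if e.draft_text is None or e.final_text is None:
            missing.append(e.message_id)
            continue
        cat = compare(e.draft_text, e.final_text, variant=variant).category
        counts[e.period][cat] += 1
    if missing:
        raise InputError(
            "seen+used events missing draft/final text: " + ", ".join(missing[:20])
            + ("..." if len(missing) > 20 else "")
        )
    return ContingencyTable(
        row_labels=tuple(c.value for c in CATEGORY_ORDER),
        col_labels=tuple(periods),
        counts=tuple(
            tuple(counts[p][c] for p in periods) for c in CATEGORY_ORDER
        ),
    )


# ---------------------------------------------------------------------------
# tests of association
# ---------------------------------------------------------------------------

def chi_square_independence(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square test of independence (no continuity correction).

    Returns (statistic, degrees of freedom, upper-tail p-value); requires
    every expected cell count to be positive.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise InputError("table has a zero marginal; expected counts undefined")
    res = stats.chi2_contingency(arr, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def odds_ratio_2x2(
    table: ContingencyTable | Sequence[Sequence[float]],
    continuity: bool = False,
    conf_level: float = 0.95,
) -> tuple[float, float, float]:
    """Unadjusted odds ratio for a 2 x 2 table [[a, b], [c, d]] with a Wald
    confidence interval on the log scale.

    OR = (a*d)/(b*c), comparing the odds of column 0 in row 0 vs row 1.
    Zero cells are an error unless ``continuity=True`` adds 0.5 to every
    cell (Haldane-Anscombe correction).  This is the marginal estimate; it
    does not adjust for clustering by provider.
    """
    arr = (
        table.as_array().astype(float)
        if isinstance(table, ContingencyTable)
        else np.asarray(table, dtype=float)
    )
    if arr.shape != (2, 2):
        raise InputError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr == 0).any():
        if not continuity:
            raise InputError(
                "zero cell in 2x2 table; pass continuity=True for the +0.5 correction"
            )
        arr = arr + 0.5
    a, b = arr[0]
    c, d = arr[1]
    or_ = (a * d) / (b * c)
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    z = float(stats.norm.ppf(0.5 + conf_level / 2))
    lo = float(np.exp(np.log(or_) - z * se))
    hi = float(np.exp(np.log(or_) + z * se))
    return float(or_), lo, hi


def usage_2x2(events: Sequence[MessageEvent], period_a: str = "post",
              period_b: str = "pre") -> ContingencyTable:
    """2x2 used/unused counts with rows (period_a, period_b)."""
    rows = []
    for p in (period_a, period_b):
        sub = [e for e in events if e.period == p]
        used = sum(e.used for e in sub)
        rows.append((used, len(sub) - used))
    return ContingencyTable(
        row_labels=(period_a, period_b),
        col_labels=("used", "not_used"),
        counts=tuple(rows),
    )


def sentiment_2x2(events: Sequence[MessageEvent], period_a: str = "post",
                  period_b: str = "pre") -> ContingencyTable:
    """2x2 negative/non-negative sentiment counts over seen messages."""
    rows = []
    for p in (period_a, period_b):
        sub = [e for e in events if e.period == p and e.seen]
        neg = sum(bool(e.sentiment_negative) for e in sub)
        rows.append((neg, len(sub) - neg))
    return ContingencyTable(
        row_labels=(period_a, period_b),
        col_labels=("negative", "not_negative"),
        counts=tuple(rows),
    )
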