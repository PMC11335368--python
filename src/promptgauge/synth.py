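"""Synthetic message-event corpora with the statistical structure the
analytics assume.

Two generators are provided:

* :func:`generate_corpus` — a stochastic corpus from a random-intercept
  usage model: provider ``i`` draws an intercept ``b_i ~ Normal(0, sd^2)``
  on the logit scale, and each of their drafts is used with probability
  ``logistic(base + period_effect * [post] + b_i)``.  Negative-sentiment
  flags are Bernoulli at a per-period rate.  Used drafts get a
  provider-edited final text at a controlled edit intensity (a target
  edit-category band drawn from ``band_mix``); discarded drafts keep no
  final text.  The logit-normal structure mirrors the generalized linear
  mixed model a pre-post clinic study would fit, so the corpus is a valid
  fixture for anyone adding mixed-model estimation later.
* :func:`corpus_from_table` — a deterministic corpus engineered to hit
  exact per-period category/usage/sentiment counts, for reconstructing
  printed summary tables cell-for-cell.

Draft texts are plain word-salad from a small packaged vocabulary: clinical
realism is a non-goal — only string-metric and statistical structure matter.
Everything is reproducible bit-for-bit from the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .analytics import MessageEvent
from .backends import stable_subseed
from .editdist import EditCategory, compare
from .errors import InputError

__all__ = [
    "SynthConfig",
    "SynthCorpus",
    "generate_corpus",
    "apply_targeted_edits",
    "corpus_from_table",
]

_BANDS = (
    EditCategory.IDENTICAL,
    EditCategory.NEARLY_IDENTICAL,
    EditCategory.SIMILAR,
    EditCategory.DIFFERENT,
)

# band midpoints used as initial targets when choosing an edit count
_BAND_TARGET_SIM = {
    EditCategory.IDENTICAL: 1.0,
    EditCategory.NEARLY_IDENTICAL: 0.987,
    EditCategory.SIMILAR: 0.82,
    EditCategory.DIFFERENT: 0.45,
}
_BAND_RANGE = {
    EditCategory.IDENTICAL: (0.9999, 1.0),
    EditCategory.NEARLY_IDENTICAL: (0.9750, 0.9999),
    EditCategory.SIMILAR: (0.6666, 0.9750),
    EditCategory.DIFFERENT: (0.0, 0.6666),
}

_WORDS = (
    "thank you for your message results look normal please continue the "
    "current plan and call the clinic if symptoms change rest fluids and "
    "time will help your refill was sent to the pharmacy today schedule a "
    "visit if the pain does not improve we will review at the next "
    "appointment take care"
).split()


@dataclass(frozen=True)
class SynthConfig:
    """Study-scale defaults: 27 providers, ~140 drafts per provider per
    period across a pre and a post period, ~17-20% usage with modest
    provider heterogeneity, sentiment dropping from 12% to 8.2%, and a
    used-draft edit mix dominated by heavy edits."""

    n_providers: int = 27
    messages_per_provider_mean: float = 140.0
    provider_intercept_sd: float = 0.8
    base_usage_logit: float = -1.45  # logistic(-1.45) ~ 0.19
    period_usage_effect: float = -0.3
    sentiment_rate_pre: float = 0.12
    sentiment_rate_post: float = 0.082
    band_mix: tuple[float, float, float, float] = (0.014, 0.139, 0.378, 0.469)
    draft_length_range: tuple[int, int] = (60, 120)
    seed: int = 0
    poisson_counts: bool = True
    with_texts: bool = True
    variant: str = "osa"

    def __post_init__(self) -> None:
        if self.n_providers < 1 or self.messages_per_provider_mean <= 0:
            raise InputError("n_providers and messages_per_provider_mean must be positive")
        if self.provider_intercept_sd < 0:
            raise InputError("provider_intercept_sd must be non-negative")
        for r in (self.sentiment_rate_pre, self.sentiment_rate_post):
            if not (0 < r < 1):
                raise InputError("sentiment rates must lie in (0, 1)")
        if len(self.band_mix) != 4 or any(w < 0 for w in self.band_mix):
            raise InputError("band_mix must be 4 non-negative weights")
        if abs(sum(self.band_mix) - 1.0) > 1e-9:
            raise InputError("band_mix must sum to 1")
        lo, hi = self.draft_length_range
        if not (4 <= lo <= hi):
            raise InputError("draft_length_range must satisfy 4 <= lo <= hi")


@dataclass(frozen=True)
class SynthCorpus:
    """Generated events plus the ground truth needed to recompute expected
    summaries: the config, realized provider intercepts, and each used
    event's target edit band."""

    events: tuple[MessageEvent, ...]
    config: SynthConfig
    provider_intercepts: Mapping[str, float]
    target_bands: Mapping[str, str]


def _draft_text(rng: np.random.Generator, n_chars: int) -> str:
    words: list[str] = []
    length = 0
    while length < n_chars:
        w = _WORDS[int(rng.integers(len(_WORDS)))]
        words.append(w)
        length += len(w) + 1
    return " ".join(words)[:n_chars].rstrip() or "take care"


_ALPHABET = "abcdefghijklmnopqrstuvwxyz "


def _mutate(text: str, k: int, rng: np.random.Generator) -> str:
    """Apply k unit edits (substitute/insert/delete/adjacent transpose)."""
    chars = list(text)
    for _ in range(k):
        op = int(rng.integers(4))
        if not chars:
            op = 1  # only insertion possible
        if op == 0:  # substitute
            i = int(rng.integers(len(chars)))
            chars[i] = _ALPHABET[int(rng.integers(len(_ALPHABET)))]
        elif op == 1:  # insert
            i = int(rng.integers(len(chars) + 1))
            chars.insert(i, _ALPHABET[int(rng.integers(len(_ALPHABET)))])
        elif op == 2 and len(chars) > 1:  # delete
            i = int(rng.integers(len(chars)))
            del chars[i]
        elif len(chars) > 1:  # transpose adjacent
            i = int(rng.integers(len(chars) - 1))
            chars[i], chars[i + 1] = chars[i + 1], chars[i]
    return "".join(chars)


def apply_targeted_edits(
    text: str,
    target_band: EditCategory | str,
    seed: int,
    variant: str = "osa",
    max_attempts: int = 20,
) -> str:
    """Edit ``text`` so its normalized similarity to the original falls in
    ``target_band``, verified by recomputation.

    Chooses an edit count k from the band's target similarity (distance is
    at most k, since each mutation is one unit operation), mutates, checks,
    and retries with k adjusted up/down for a bounded number of attempts.
    Raises :class:`InputError` for text shorter than 4 characters or a band
    the text length cannot reach (e.g. nearly-identical needs ~40+
    characters for a single edit to stay above 0.975).
    """
    band = EditCategory(target_band)
    if len(text) < 4:
        raise InputError("text must be at least 4 characters")
    if band is EditCategory.IDENTICAL:
        return text
    lo, hi = _BAND_RANGE[band]
    n = len(text)
    k = max(1, round(n * (1.0 - _BAND_TARGET_SIM[band])))
    for attempt in range(max_attempts):
        rng = np.random.default_rng(stable_subseed(seed, "edits", attempt))
        edited = _mutate(text, k, rng)
        sim = compare(text, edited, variant=variant).similarity
        if lo <= sim < hi:
            return edited
        # adjust: too similar -> more edits; too different -> fewer
        if sim >= hi:
            k += max(1, math.ceil(n * (sim - hi)))
        else:
            k = max(1, k - max(1, math.ceil(n * (lo - sim) / 2)))
    raise InputError(
        f"could not reach band {band.value!r} for text of length {n} "
        f"after {max_attempts} attempts"
    )


def generate_corpus(config: SynthConfig) -> SynthCorpus:
    """Draw a full corpus from the random-intercept usage model."""
    master = np.random.default_rng(stable_subseed(config.seed, "corpus"))
    intercepts = {
        f"prov{i:03d}": float(b)
        for i, b in enumerate(
            master.normal(0.0, config.provider_intercept_sd, size=config.n_providers)
        )
    }
    events: list[MessageEvent] = []
    target_bands: dict[str, str] = {}
    band_p = np.asarray(config.band_mix, dtype=float)
    band_p = band_p / band_p.sum()
    lo_len, hi_len = config.draft_length_range
    counter = 0
    for pid, b_i in intercepts.items():
        for period in ("pre", "post"):
            rng = np.random.default_rng(stable_subseed(config.seed, "prov", pid, period))
            if config.poisson_counts:
                n_msgs = int(rng.poisson(config.messages_per_provider_mean))
            else:
                n_msgs = int(round(config.messages_per_provider_mean))
            eta = config.base_usage_logit + b_i
            if period == "post":
                eta += config.period_usage_effect
            p_use = 1.0 / (1.0 + math.exp(-eta))
            p_neg = (
                config.sentiment_rate_pre if period == "pre" else config.sentiment_rate_post
            )
            for _ in range(n_msgs):
                mid = f"msg{counter:06d}"
                counter += 1
                used = bool(rng.random() < p_use)
                neg = bool(rng.random() < p_neg)
                draft = final = None
                if config.with_texts:
                    n_chars = int(rng.integers(lo_len, hi_len + 1))
                    draft = _draft_text(rng, n_chars)
                    if used:
                        band = _BANDS[int(rng.choice(4, p=band_p))]
                        final = apply_targeted_edits(
                            draft, band, stable_subseed(config.seed, "band", mid),
                            variant=config.variant,
                        )
                        target_bands[mid] = band.value
                events.append(
                    MessageEvent(
                        message_id=mid,
                        provider_id=pid,
                        period=period,
                        seen=True,
                        used=used,
                        sentiment_negative=neg,
                        draft_text=draft,
                        final_text=final,
                    )
                )
    return SynthCorpus(
        events=tuple(events),
        config=config,
        provider_intercepts=intercepts,
        target_bands=target_bands,
    )


def corpus_from_table(
    category_counts: Mapping[str, Mapping[str, int]],
    used_counts: Mapping[str, int],
    sentiment_counts: Mapping[str, int] | None = None,
    seed: int = 0,
    draft_length: int = 60,
    n_providers: int = 9,
    extra_periods: Mapping[str, tuple[int, int]] | None = None,
) -> list[MessageEvent]:
    """Engineer a corpus hitting exact per-period counts.

    ``category_counts`` maps period -> {identical, nearly_identical,
    similar, different} cell counts over *seen* messages; ``used_counts``
    gives used messages per period.  Used messages beyond the first three
    bands are generated as heavily edited ("different"); the remaining
    "different" cell is filled with unused drafts.  ``sentiment_counts``
    assigns exactly that many negative flags per period.
    ``extra_periods`` maps additional period names (e.g. "phase3") to
    (total, used) pairs without edit-category structure.

    The resulting corpus reproduces the requested table cell-for-cell under
    :func:`promptgauge.analytics.edit_category_table`.
    """
    events: list[MessageEvent] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        mid = f"fix{counter:06d}"
        counter += 1
        return mid

    for period, cells in category_counts.items():
        total = sum(cells.values())
        used = used_counts[period]
        in_band_used = (
            cells.get("identical", 0)
            + cells.get("nearly_identical", 0)
            + cells.get("similar", 0)
        )
        if used < in_band_used or used > total:
            raise InputError(
                f"period {period!r}: used={used} inconsistent with category cells"
            )
        used_different = used - in_band_used
        unused = total - used
        if cells.get("different", 0) != used_different + unused:
            raise InputError(
                f"period {period!r}: 'different' cell must equal "
                f"(used - first three bands) + unused"
            )
        plan: list[tuple[EditCategory, bool]] = []
        for band_name in ("identical", "nearly_identical", "similar"):
            plan += [(EditCategory(band_name), True)] * cells.get(band_name, 0)
        plan += [(EditCategory.DIFFERENT, True)] * used_different
        plan += [(EditCategory.DIFFERENT, False)] * unused

        n_neg = (sentiment_counts or {}).get(period, 0)
        for idx, (band, is_used) in enumerate(plan):
            mid = new_id()
            rng = np.random.default_rng(stable_subseed(seed, "fixture", mid))
            draft = _draft_text(rng, draft_length)
            final = None
            if is_used:
                final = apply_targeted_edits(
                    draft, band, stable_subseed(seed, "fixband", mid)
                )
            events.append(
                MessageEvent(
                    message_id=mid,
                    provider_id=f"prov{idx % n_providers:03d}",
                    period=period,
                    seen=True,
                    used=is_used,
                    sentiment_negative=idx < n_neg,
                    draft_text=draft,
                    final_text=final,
                )
            )

    for period, (total, used) in (extra_periods or {}).items():
        for idx in range(total):
            events.append(
                MessageEvent(
                    message_id=new_id(),
                    provider_id=f"prov{idx % n_providers:03d}",
                    period=period,
                    seen=True,
                    used=idx < used,
                )
            )
    return events
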