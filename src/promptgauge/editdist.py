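"""Damerau-Levenshtein edit distances, normalized similarity, and the
four-band edit categorization used to grade how heavily providers edit
AI-drafted replies.

Two variants are implemented:

* **OSA** (optimal string alignment) — insertions, deletions, substitutions
  and adjacent transpositions, with the restriction that no substring is
  edited twice.  This is what most libraries mean by "Damerau-Levenshtein";
  it is the package default but is *not* a metric (it can violate the
  triangle inequality).
* **unrestricted DL** — the true Damerau-Levenshtein distance
  (Lowrance-Wagner), in which transposed characters may be edited further.
  It satisfies all metric axioms and is never larger than the OSA distance.

Distances are computed on NFC-normalized Unicode code points with unit cost
for every operation; case and whitespace are significant.  Similarity is
``1 - d / max(len(a), len(b))`` (1.0 for two empty strings), and the bands
partition [0, 1]::

    identical        s >= 0.9999
    nearly_identical 0.9750 <= s < 0.9999
    similar          0.6666 <= s < 0.9750
    different        s < 0.6666

The published band definitions leave exactly 0.9999 unassigned (">0.9999"
vs "<0.9999"); this implementation closes the upper band, so 0.9999 counts
as identical.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from enum import Enum

from .errors import InputError

__all__ = [
    "EditCategory",
    "EditComparison",
    "BAND_IDENTICAL",
    "BAND_NEARLY_IDENTICAL",
    "BAND_SIMILAR",
    "osa_distance",
    "dl_distance_unrestricted",
    "levenshtein_distance",
    "normalized_similarity",
    "categorize",
    "compare",
]

# Band thresholds on normalized similarity; immutable by convention.
BAND_IDENTICAL = 0.9999
BAND_NEARLY_IDENTICAL = 0.9750
BAND_SIMILAR = 0.6666


class EditCategory(str, Enum):
    IDENTICAL = "identical"
    NEARLY_IDENTICAL = "nearly_identical"
    SIMILAR = "similar"
    DIFFERENT = "different"


@dataclass(frozen=True)
class EditComparison:
    """Draft-vs-final comparison: raw distance, similarity, category band."""

    draft_text: str
    final_text: str
    distance: int
    similarity: float
    category: EditCategory
    variant: str  # "osa" or "unrestricted_dl"


def _nfc(s: str) -> str:
    return unicodedata.normalize("NFC", s)


def levenshtein_distance(a: str, b: str) -> int:
    """Plain Levenshtein distance (no transpositions), unit costs."""
    a, b = _nfc(a), _nfc(b)
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, start=1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (ca != cb),
            )
        prev = cur
    return prev[-1]


def osa_distance(a: str, b: str) -> int:
    """Optimal-string-alignment distance.

    Unit-cost insert/delete/substitute plus adjacent transposition, with no
    substring edited twice.  Symmetric; 0 iff the (NFC-normalized) strings
    are equal; bounded by ``|len(a)-len(b)| <= d <= max(len(a), len(b))``.
    """
    a, b = _nfc(a), _nfc(b)
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    n = len(b)
    prev2: list[int] = []
    prev = list(range(n + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cb = b[j - 1]
            d = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            if i > 1 and j > 1 and ca == b[j - 2] and a[i - 2] == cb:
                d = min(d, prev2[j - 2] + 1)
            cur[j] = d
        prev2, prev = prev, cur
    return prev[-1]


def dl_distance_unrestricted(a: str, b: str) -> int:
    """True (unrestricted) Damerau-Levenshtein distance, Lowrance-Wagner.

    Transposed characters may be edited again, so this is a genuine metric
    (triangle inequality holds) and is pointwise <= the OSA distance.
    """
    a, b = _nfc(a), _nfc(b)
    if a == b:
        return 0
    la, lb = len(a), len(b)
    if not la:
        return lb
    if not lb:
        return la
    maxdist = la + lb
    # d has a sentinel row/column of `maxdist` at index 0; string indices
    # are offset by +1 (classic Lowrance-Wagner layout).
    d = [[0] * (lb + 2) for _ in range(la + 2)]
    d[0][0] = maxdist
    for i in range(la + 1):
        d[i + 1][0] = maxdist
        d[i + 1][1] = i
    for j in range(lb + 1):
        d[0][j + 1] = maxdist
        d[1][j + 1] = j
    last_row: dict[str, int] = {}
    for i in range(1, la + 1):
        last_col = 0  # last column in b matching a[i-1], seen so far this row
        for j in range(1, lb + 1):
            i_prev, j_prev = last_row.get(b[j - 1], 0), last_col
            cost = 0 if a[i - 1] == b[j - 1] else 1
            if cost == 0:
                last_col = j
            d[i + 1][j + 1] = min(
                d[i][j] + cost,  # substitute / match
                d[i + 1][j] + 1,  # insert
                d[i][j + 1] + 1,  # delete
                # transpose a[i_prev-1]..a[i-1] with everything between
                d[i_prev][j_prev] + (i - i_prev - 1) + 1 + (j - j_prev - 1),
            )
        last_row[a[i - 1]] = i
    return d[la + 1][lb + 1]


_DISTANCE_FNS = {
    "osa": osa_distance,
    "unrestricted_dl": dl_distance_unrestricted,
}


def normalized_similarity(a: str, b: str, variant: str = "osa") -> float:
    """``1 - d(a, b) / max(len(a), len(b))`` in [0, 1]; 1.0 for two empties."""
    try:
        fn = _DISTANCE_FNS[variant]
    except KeyError:
        raise InputError(f"unknown distance variant {variant!r}") from None
    a, b = _nfc(a), _nfc(b)
    denom = max(len(a), len(b))
    if denom == 0:
        return 1.0
    return 1.0 - fn(a, b) / denom


def categorize(similarity: float) -> EditCategory:
    """Assign the edit-category band for a similarity in [0, 1]."""
    if not (0.0 <= similarity <= 1.0):
        raise InputError(f"similarity must be in [0, 1], got {similarity}")
    if similarity >= BAND_IDENTICAL:
        return EditCategory.IDENTICAL
    if similarity >= BAND_NEARLY_IDENTICAL:
        return EditCategory.NEARLY_IDENTICAL
    if similarity >= BAND_SIMILAR:
        return EditCategory.SIMILAR
    return EditCategory.DIFFERENT


def compare(draft: str, final: str, variant: str = "osa") -> EditComparison:
    """Full draft-vs-final comparison with all fields populated consistently."""
    try:
        fn = _DISTANCE_FNS[variant]
    except KeyError:
        raise InputError(f"unknown distance variant {variant!r}") from None
    d = fn(draft, final)
    a, b = _nfc(draft), _nfc(final)
    denom = max(len(a), len(b))
    sim = 1.0 if denom == 0 else 1.0 - d / denom
    return EditComparison(
        draft_text=draft,
        final_text=final,
        distance=d,
        similarity=sim,
        category=categorize(sim),
        variant=variant,
    )
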