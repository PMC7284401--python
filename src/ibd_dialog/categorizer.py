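"""Rule-based multi-label assignment, frequency reporting, and category overlap.

A line receives every category for which at least one keyword scores
positively in its bag-of-words; a line matching nothing falls back to
miscellaneous. Because one line can hit several categories, per-category
percentages are computed against the number of lines and deliberately sum to
more than 100. Pairwise co-occurrence is tabulated as a symmetric matrix with
solo counts (lines labeled with exactly one category) on the diagonal —
higher-order overlap exists but is not tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .dialog_io import DialogRecord
from .labels import LabelSet, make_label_set
from .lexicon import Lexicon
from .text_prep import TokenBag, normalize_tokens, tokenize


def percent_of(count: int, denominator: int) -> float:
    """count/denominator as a percentage, rounded half-up to 2 decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    frac = Decimal(count) * 100 / Decimal(denominator)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _phrase_in(sequence: Sequence[str], phrase: Sequence[str]) -> bool:
    n, m = len(sequence), len(phrase)
    return any(list(sequence[i : i + m]) == list(phrase) for i in range(n - m + 1))


def categorize_line(bag: TokenBag, raw_content: str, lexicon: Lexicon) -> LabelSet:
    """Assign every category with a positively scored keyword; else fallback.

    Unigram keywords are looked up in the stop-word-filtered bag; multi-word
    keywords are matched as contiguous runs in the normalized raw line (stop
    words retained there, so phrases like "follow up" survive).
    """
    tokens = bag.tokens()
    sequence = normalize_tokens(raw_content)
    codes: set[int] = set()
    for cat in lexicon.categories:
        if cat.fallback:
            continue
        for kw in cat.keywords:
            if " " in kw:
                if _phrase_in(sequence, kw.split()):
                    codes.add(cat.code)
                    break
            elif kw in tokens:
                codes.add(cat.code)
                break
    if not codes:
        codes = {lexicon.fallback_code}
    return make_label_set(codes, lexicon.fallback_code)


def categorize_corpus(
    records: Sequence[DialogRecord],
    lexicon: Lexicon,
    stop_words: frozenset[str] | None = None,
) -> dict[str, LabelSet]:
    """Label every (already exclusion-filtered) record; one label set per line."""
    labels: dict[str, LabelSet] = {}
    for rec in records:
        bag = tokenize(rec.content, stop_words, source_identifier=rec.identifier)
        labels[rec.identifier] = categorize_line(bag, rec.content, lexicon)
    return labels


@dataclass(frozen=True)
class CategoryReport:
    """Per-category line counts and percentages of a common denominator."""

    denominator: int
    per_category: dict[int, tuple[int, float]]

    def to_frame(self, lexicon: Lexicon | None = None) -> pd.DataFrame:
        rows = [
            {
                "code": code,
                "category": lexicon.name_of(code) if lexicon else str(code),
                "count": count,
                "percent": pct,
            }
            for code, (count, pct) in sorted(self.per_category.items())
        ]
        return pd.DataFrame(rows, columns=["code", "category", "count", "percent"])


def frequency_report(
    labels: Mapping[str, LabelSet],
    lexicon: Lexicon | None = None,
) -> CategoryReport:
    """Count lines containing each category; percentages are of all lines.

    Overlapping labels mean the percentages can sum past 100 — each line is
    counted once per category it carries.
    """
    if not labels:
        raise ValueError("labels must be non-empty")
    denominator = len(labels)
    codes: Iterable[int]
    if lexicon is not None:
        codes = lexicon.codes
    else:
        codes = sorted({c for ls in labels.values() for c in ls})
    per_category = {}
    for code in codes:
        count = sum(1 for ls in labels.values() if code in ls)
        per_category[code] = (count, percent_of(count, denominator))
    return CategoryReport(denominator=denominator, per_category=per_category)


def overlap_matrix(labels: Mapping[str, LabelSet], lexicon: Lexicon) -> pd.DataFrame:
    """Symmetric pairwise co-occurrence counts over non-fallback categories.

    ``M[a, b]`` (a != b) counts lines labeled with both a and b; the diagonal
    ``M[a, a]`` counts lines labeled with exactly {a}. Fallback-labeled lines
    do not appear.
    """
    if not labels:
        raise ValueError("labels must be non-empty")
    codes = list(lexicon.non_fallback_codes)
    m = pd.DataFrame(0, index=codes, columns=codes, dtype=int)
    fallback = lexicon.fallback_code
    for ls in labels.values():
        if fallback in ls:
            continue
        ordered = sorted(ls)
        if len(ordered) == 1:
            a = ordered[0]
            m.loc[a, a] += 1
        else:
            for i, a in enumerate(ordered):
                for b in ordered[i + 1 :]:
                    m.loc[a, b] += 1
                    m.loc[b, a] += 1
    return m
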