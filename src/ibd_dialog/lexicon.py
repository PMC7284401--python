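"""Category definitions, the keyword lexicon, and frequency-based keyword mining.

A lexicon is an ordered list of categories with consecutive 1-based codes.
Exactly one category (miscellaneous) is the fallback: it has no keywords and
collects lines matching nothing else. Keywords are normalized token sequences;
single tokens match through the bag-of-words, multi-word phrases match as
contiguous token runs in the original line. A keyword may appear in several
categories — category overlap is a feature of the scheme, not an error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .resources import default_lexicon_text, default_stop_words
from .text_prep import TokenBag, normalize_line


@dataclass(frozen=True)
class CategoryDef:
    code: int
    name: str
    keywords: frozenset[str]
    fallback: bool = False


@dataclass(frozen=True)
class Lexicon:
    categories: tuple[CategoryDef, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        codes = [c.code for c in self.categories]
        if codes != list(range(1, len(codes) + 1)):
            raise ValueError("category codes must be consecutive from 1 in lexicon order")
        names = [c.name for c in self.categories]
        if len(set(names)) != len(names):
            raise ValueError("category names must be unique")
        fallbacks = [c for c in self.categories if c.fallback]
        if len(fallbacks) != 1:
            raise ValueError("exactly one fallback category is required")
        if fallbacks[0].keywords:
            raise ValueError("the fallback category must have no keywords")
        for cat in self.categories:
            if not cat.fallback and not cat.keywords:
                raise ValueError(f"non-fallback category {cat.name!r} has no keywords")

    @property
    def fallback_code(self) -> int:
        return next(c.code for c in self.categories if c.fallback)

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(c.code for c in self.categories)

    @property
    def non_fallback_codes(self) -> tuple[int, ...]:
        return tuple(c.code for c in self.categories if not c.fallback)

    def by_code(self, code: int) -> CategoryDef:
        try:
            return self.categories[code - 1]
        except IndexError:
            raise KeyError(f"no category with code {code}") from None

    def name_of(self, code: int) -> str:
        return self.by_code(code).name


def _normalize_keyword(raw: str) -> str:
    kw = normalize_line(raw)
    if not kw:
        raise ValueError(f"keyword {raw!r} normalizes to nothing")
    return kw


def build_lexicon(
    entries: Iterable[Mapping],
    stop_words: frozenset[str] | None = None,
) -> Lexicon:
    """Assemble and validate a lexicon from parsed category entries."""
    if stop_words is None:
        stop_words = default_stop_words()
    seen_codes: set[int] = set()
    cats: list[CategoryDef] = []
    for entry in entries:
        code = int(entry["code"])
        if code in seen_codes:
            raise ValueError(f"duplicate category code {code}")
        seen_codes.add(code)
        keywords = frozenset(_normalize_keyword(k) for k in entry.get("keywords", []))
        for kw in keywords:
            if kw in stop_words:
                raise ValueError(f"keyword {kw!r} is a stop word")
        cats.append(
            CategoryDef(
                code=code,
                name=str(entry["name"]),
                keywords=keywords,
                fallback=bool(entry.get("fallback", False)),
            )
        )
    cats.sort(key=lambda c: c.code)
    return Lexicon(categories=tuple(cats))


def load_lexicon(
    source: str | Path | None = None,
    stop_words: frozenset[str] | None = None,
) -> Lexicon:
    """Load a lexicon from a JSON file; with no source, the shipped default.

    Schema: ``{"categories": [{"code": int, "name": str, "fallback": bool,
    "keywords": [str, ...]}, ...]}``. The shipped default covers the final
    eight-category scheme (symptoms, medications, appointments, laboratory
    investigations, finance/insurance, communications, procedures, and
    miscellaneous as fallback) with stand-in clinical vocabulary.
    """
    if source is None:
        payload = json.loads(default_lexicon_text())
    else:
        payload = json.loads(Path(source).read_text(encoding="utf-8"))
    return build_lexicon(payload["categories"], stop_words)


def mine_keywords(
    labeled_lines: Iterable[tuple[TokenBag, frozenset[int]]],
    threshold: int = 10,
) -> dict[int, list[tuple[str, int]]]:
    """Propose candidate keywords per category by summed term frequency.

    A token is proposed for a category when its count, summed over all lines
    labeled with that category, reaches ``threshold`` (default 10). Candidates
    are ranked by frequency descending, ties broken lexicographically. Output
    is advisory — in practice a clinician reviews the proposals before they
    enter the lexicon.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    labeled_lines = list(labeled_lines)
    if not labeled_lines:
        raise ValueError("labeled_lines must be non-empty")
    totals: dict[int, dict[str, int]] = {}
    for bag, labels in labeled_lines:
        for code in labels:
            acc = totals.setdefault(code, {})
            for token, count in bag.counts.items():
                acc[token] = acc.get(token, 0) + count
    return {
        code: sorted(
            ((t, n) for t, n in acc.items() if n >= threshold),
            key=lambda tn: (-tn[1], tn[0]),
        )
        for code, acc in sorted(totals.items())
    }
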