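"""Tokenization, bag-of-words construction, and exclusion filtering.

Lines are lower-cased and split on non-alphanumeric boundaries; stop words are
removed before counting. Two kinds of uninformative lines are filtered out
ahead of categorization:

* greeting-only lines ("Thank you", "Hello", "thanks!!") — every informative
  (non-stop-word) token belongs to the greeting vocabulary;
* platform-automated lines ("Patient has indicated there are no changes to
  medications.") — exact match against a fixed template list after
  normalization, since the app emits them verbatim.

Automated matching is tested first; a line with no informative tokens at all
is treated as greeting-only.
"""

from __future__ import annotations

import enum
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .resources import (
    default_automated_templates,
    default_greeting_templates,
    default_stop_words,
)

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def normalize_tokens(content: str) -> list[str]:
    """Lower-case and split on non-alphanumeric boundaries; keeps stop words."""
    return _TOKEN_RE.findall(content.lower())


def normalize_line(content: str) -> str:
    """Canonical single-spaced form of a line, for exact template matching."""
    return " ".join(normalize_tokens(content))


@dataclass(frozen=True)
class TokenBag:
    """Bag-of-words for one line: token -> raw term frequency (stop words removed)."""

    counts: dict[str, int] = field(default_factory=dict)
    source_identifier: str = ""

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("token counts must be >= 1")

    def tokens(self) -> frozenset[str]:
        return frozenset(self.counts)

    def __len__(self) -> int:
        return sum(self.counts.values())


class ExclusionReason(enum.Enum):
    GREETING_ONLY = "greeting_only"
    AUTOMATED = "automated"
    NONE = "none"


def tokenize(
    content: str,
    stop_words: frozenset[str] | None = None,
    *,
    source_identifier: str = "",
) -> TokenBag:
    """Build the bag-of-words for one line.

    Counts are raw term frequencies after case folding and stop-word removal;
    empty content yields an empty bag.
    """
    if stop_words is None:
        stop_words = default_stop_words()
    counts = Counter(t for t in normalize_tokens(content) if t not in stop_words)
    return TokenBag(counts=dict(counts), source_identifier=source_identifier)


def greeting_vocabulary(greeting_templates: Iterable[str]) -> frozenset[str]:
    """Token vocabulary spanned by the greeting templates."""
    vocab: set[str] = set()
    for template in greeting_templates:
        vocab.update(normalize_tokens(template))
    return frozenset(vocab)


def classify_exclusion(
    content: str,
    greeting_templates: Sequence[str] | None = None,
    automated_templates: Sequence[str] | None = None,
    stop_words: frozenset[str] | None = None,
) -> ExclusionReason:
    """Decide whether a line is automated, greeting-only, or informative.

    Automated lines match a template exactly after normalization. A line is
    greeting-only when all of its non-stop-word tokens lie in the greeting
    vocabulary (so repeated or punctuated greetings are still excluded).
    """
    if greeting_templates is None:
        greeting_templates = default_greeting_templates()
    if automated_templates is None:
        automated_templates = default_automated_templates()
    if not greeting_templates or not automated_templates:
        raise ValueError("template sets must be non-empty")
    if stop_words is None:
        stop_words = default_stop_words()

    normalized = normalize_line(content)
    automated = {normalize_line(t) for t in automated_templates}
    if normalized and normalized in automated:
        return ExclusionReason.AUTOMATED

    informative = [t for t in normalize_tokens(content) if t not in stop_words]
    vocab = greeting_vocabulary(greeting_templates)
    if all(t in vocab for t in informative):
        return ExclusionReason.GREETING_ONLY
    return ExclusionReason.NONE


def apply_exclusions(
    records: Sequence,
    greeting_templates: Sequence[str] | None = None,
    automated_templates: Sequence[str] | None = None,
    stop_words: frozenset[str] | None = None,
):
    """Partition records into kept lines and excluded greeting/automated lines.

    Returns ``(kept, excluded_count, reasons)`` where ``reasons`` maps every
    record identifier to its :class:`ExclusionReason`. ``kept`` preserves the
    input order; counts conserve (kept + excluded == input size).
    """
    kept = []
    reasons: dict[str, ExclusionReason] = {}
    for record in records:
        verdict = classify_exclusion(
            record.content, greeting_templates, automated_templates, stop_words
        )
        reasons[record.identifier] = verdict
        if verdict is ExclusionReason.NONE:
            kept.append(record)
    return kept, len(records) - len(kept), reasons
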