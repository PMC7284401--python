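"""Label sets and their canonical digit-string codes.

A line's label set is a frozenset of category codes. Its canonical serialized
form is the codes in ascending numeric order with no separators ("134") — the
same style human raters use on their sheets. The fallback (miscellaneous)
code, when present, must be the only code: a line is miscellaneous precisely
because nothing else matched.
"""

from __future__ import annotations

from typing import Iterable, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .lexicon import Lexicon

LabelSet = frozenset[int]


def make_label_set(codes: Iterable[int], fallback_code: int | None = None) -> LabelSet:
    """Validate and freeze a label set (non-empty; fallback only stands alone)."""
    labels = frozenset(int(c) for c in codes)
    if not labels:
        raise ValueError("a label set must be non-empty")
    if fallback_code is not None and fallback_code in labels and len(labels) > 1:
        raise ValueError("the fallback code cannot be combined with other codes")
    return labels


def label_code(labels: Iterable[int]) -> str:
    """Canonical digit-string form: ascending codes, no separators."""
    return "".join(str(c) for c in sorted(set(labels)))


def parse_code(code_string: str, lexicon: "Lexicon") -> LabelSet:
    """Parse a rater-style digit string ("123") into a label set.

    Each digit must name a defined category; a repeated digit is rejected as
    ambiguous rather than silently de-duplicated.
    """
    if not code_string or not code_string.isdigit():
        raise ValueError(f"code string must be a non-empty digit string, got {code_string!r}")
    codes = [int(ch) for ch in code_string]
    if len(set(codes)) != len(codes):
        raise ValueError(f"repeated digit in code string {code_string!r}")
    defined = set(lexicon.codes)
    for code in codes:
        if code not in defined:
            raise ValueError(f"code {code} names no defined category")
    return make_label_set(codes, lexicon.fallback_code)
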