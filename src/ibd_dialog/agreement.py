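"""Algorithm-versus-rater comparison and inter-rater reliability.

Per line, the comparison against one rater counts overclassifications (codes
the algorithm added beyond the rater) and underclassifications (codes it
missed). A nonzero difference is *minor* when the line has at most 2
overclassifications and at most 1 underclassification — the domain judgment
being that adding a secondary topic is cheap while missing the rater's intent
is not — and *major* otherwise. The headline accuracy figure is the fraction
of lines with minor or no differences.

Agreement among the raters themselves is Krippendorff's alpha for nominal
data, computed from the coincidence matrix (alpha = 1 − D_o/D_e). Each unit's
value is the whole canonical label-code string, so "12" versus "1" is simply
a disagreement. A per-category binary variant (alpha per category,
macro-averaged) is available for sensitivity analysis.
"""

from __future__ import annotations

import csv
import enum
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .labels import LabelSet, label_code, parse_code
from .lexicon import Lexicon

#: severity thresholds for a "minor" difference
MINOR_MAX_OVER = 2
MINOR_MAX_UNDER = 1


class Severity(enum.Enum):
    NONE = "none"
    MINOR = "minor"
    MAJOR = "major"


@dataclass(frozen=True)
class LineComparison:
    over: int
    under: int

    def __post_init__(self) -> None:
        if self.over < 0 or self.under < 0:
            raise ValueError("difference counts must be non-negative")

    @property
    def severity(self) -> Severity:
        if self.over == 0 and self.under == 0:
            return Severity.NONE
        if self.over <= MINOR_MAX_OVER and self.under <= MINOR_MAX_UNDER:
            return Severity.MINOR
        return Severity.MAJOR


@dataclass(frozen=True)
class RaterSheet:
    """One rater's label codes, keyed by line identifier."""

    rater_id: str
    codes: dict[str, LabelSet] = field(default_factory=dict)


@dataclass(frozen=True)
class AgreementSummary:
    n_lines: int
    over_histogram: dict[int, int]
    under_histogram: dict[int, int]
    minor_or_none_fraction: float
    alpha: float | None = None

    @property
    def total_difference_instances(self) -> int:
        """Lines contributing to either histogram (a both-sided line counts twice)."""
        return sum(self.over_histogram.values()) + sum(self.under_histogram.values())


def load_rater_sheet(source: str | Path, lexicon: Lexicon, rater_id: str | None = None) -> RaterSheet:
    """Read a rater CSV (columns line_identifier, code_string)."""
    source = Path(source)
    codes: dict[str, LabelSet] = {}
    with source.open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            codes[row["line_identifier"]] = parse_code(row["code_string"], lexicon)
    return RaterSheet(rater_id=rater_id or source.stem, codes=codes)


def compare_line(algorithm: LabelSet, rater: LabelSet) -> LineComparison:
    """Over/under-classification of the algorithm relative to one rater."""
    return LineComparison(
        over=len(algorithm - rater),
        under=len(rater - algorithm),
    )


def summarize(
    comparisons: Sequence[LineComparison],
    alpha: float | None = None,
) -> AgreementSummary:
    """Difference histograms and the minor-or-none fraction over all lines."""
    if not comparisons:
        raise ValueError("comparisons must be non-empty")
    over_hist = Counter(c.over for c in comparisons if c.over > 0)
    under_hist = Counter(c.under for c in comparisons if c.under > 0)
    ok = sum(1 for c in comparisons if c.severity in (Severity.NONE, Severity.MINOR))
    return AgreementSummary(
        n_lines=len(comparisons),
        over_histogram=dict(sorted(over_hist.items())),
        under_histogram=dict(sorted(under_hist.items())),
        minor_or_none_fraction=ok / len(comparisons),
        alpha=alpha,
    )


def summary_from_histograms(
    over_histogram: Mapping[int, int],
    under_histogram: Mapping[int, int],
    n_lines: int,
) -> AgreementSummary:
    """Rebuild the summary from published difference histograms.

    Assumes each differing line contributes to one side only (no line carries
    both an over- and an underclassification), which is how a printed
    two-column histogram is read back into per-line comparisons.
    """
    comparisons = []
    for k, count in over_histogram.items():
        if k > 0:
            comparisons.extend([LineComparison(over=k, under=0)] * count)
    for k, count in under_histogram.items():
        if k > 0:
            comparisons.extend([LineComparison(over=0, under=k)] * count)
    if len(comparisons) > n_lines:
        raise ValueError("histograms describe more lines than n_lines")
    comparisons.extend([LineComparison(over=0, under=0)] * (n_lines - len(comparisons)))
    return summarize(comparisons)


def _coincidence_alpha(units: Sequence[Sequence[str]]) -> float:
    """Nominal Krippendorff alpha from units of >= 2 ratings each."""
    o: Counter[tuple[str, str]] = Counter()
    for ratings in units:
        m = len(ratings)
        for i, ci in enumerate(ratings):
            for j, ck in enumerate(ratings):
                if i != j:
                    o[(ci, ck)] += 1.0 / (m - 1)
    n_c: Counter[str] = Counter()
    for (c, _k), v in o.items():
        n_c[c] += v
    n = sum(n_c.values())
    d_obs = sum(v for (c, k), v in o.items() if c != k) / n
    d_exp = sum(
        n_c[c] * n_c[k] for c in n_c for k in n_c if c != k
    ) / (n * (n - 1))
    if d_exp == 0.0:
        if d_obs == 0.0:
            return 1.0  # all ratings identical: perfect agreement by convention
        raise ZeroDivisionError("zero expected disagreement with observed disagreement")
    return 1.0 - d_obs / d_exp


def krippendorff_alpha(
    sheets: Sequence[RaterSheet],
    unit_ids: Iterable[str] | None = None,
    *,
    per_category: bool = False,
    lexicon: Lexicon | None = None,
) -> float:
    """Krippendorff's alpha across raters on nominal label-code values.

    Units rated by fewer than two raters are dropped. By default each unit's
    value is its canonical label-code string; with ``per_category=True`` the
    statistic is instead computed per non-fallback category on binary
    membership and macro-averaged (requires ``lexicon``).
    """
    if len(sheets) < 2:
        raise ValueError("at least 2 raters are required")
    if unit_ids is None:
        ids = sorted(set().union(*(s.codes.keys() for s in sheets)))
    else:
        ids = list(unit_ids)

    def usable_units(value_of) -> list[list[str]]:
        units = []
        for uid in ids:
            ratings = [value_of(s.codes[uid]) for s in sheets if uid in s.codes]
            if len(ratings) >= 2:
                units.append(ratings)
        return units

    if not per_category:
        units = usable_units(label_code)
        if len(units) < 2:
            raise ValueError("fewer than 2 usable units")
        return _coincidence_alpha(units)

    if lexicon is None:
        raise ValueError("per_category alpha requires a lexicon")
    alphas = []
    for code in lexicon.non_fallback_codes:
        units = usable_units(lambda ls, c=code: "1" if c in ls else "0")
        if len(units) < 2:
            raise ValueError("fewer than 2 usable units")
        try:
            alphas.append(_coincidence_alpha(units))
        except ZeroDivisionError:
            continue  # category never used and never disputed: uninformative
    if not alphas:
        raise ValueError("no category yielded a defined alpha")
    return sum(alphas) / len(alphas)
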