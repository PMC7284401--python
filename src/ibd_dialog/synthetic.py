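"""Synthetic secure-message corpora with planted category structure.

No real clinical message log ships with this package, so every downstream
stage is exercised on generated corpora whose truth is known by construction.
Each generated line is one of:

* a greeting-only line drawn from the greeting templates;
* a platform-automated line drawn from the automated templates;
* a labeled patient message: a base category is sampled from the prevalence
  weights, partner categories are added pairwise with their overlap
  probabilities, and the content is assembled from lexicon keywords of every
  truth category plus filler tokens that match no keyword. A line whose base
  is the fallback category carries filler tokens only.

Token-level structure is all the classifier consumes, so that is all the
generator emulates — no attempt is made at realistic clinical prose. The
default parameters mirror the study conditions this generator stands in for:
category weights proportional to the published final category counts, and
greeting/automated fractions reproducing the published overall exclusion rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Mapping

import numpy as np

from .dialog_io import DialogRecord, Direction, write_records
from .labels import LabelSet, label_code
from .lexicon import Lexicon
from .resources import default_automated_templates, default_greeting_templates

#: base-category sampling weights; proportional to the final per-category
#: line counts of the study population this generator emulates
DEFAULT_CATEGORY_PREVALENCE: dict[int, float] = {
    1: 2033, 2: 2397, 3: 1518, 4: 2106, 5: 447, 6: 2161, 7: 617, 8: 624,
}
_total = sum(DEFAULT_CATEGORY_PREVALENCE.values())
DEFAULT_CATEGORY_PREVALENCE = {
    c: w / _total for c, w in DEFAULT_CATEGORY_PREVALENCE.items()
}

#: pairwise overlap probabilities; qualitative emulation of the observed
#: heat map (symptoms co-occur most with medications and communications)
DEFAULT_PAIR_OVERLAP: dict[tuple[int, int], float] = {
    (1, 2): 0.30,
    (1, 6): 0.25,
    (2, 4): 0.20,
    (3, 6): 0.15,
    (5, 7): 0.10,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic corpus; same spec + seed => identical corpus."""

    n_patients: int = 50
    n_lines: int = 1000
    category_prevalence: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PREVALENCE)
    )
    pair_overlap: dict[tuple[int, int], float] = field(
        default_factory=lambda: dict(DEFAULT_PAIR_OVERLAP)
    )
    greeting_fraction: float = 0.176
    automated_fraction: float = 0.08
    keywords_per_line: int = 2
    filler_vocab_size: int = 50
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1 or self.n_lines < 1:
            raise ValueError("n_patients and n_lines must be positive")
        if self.keywords_per_line < 1:
            raise ValueError("keywords_per_line must be positive for labeled lines")
        if self.filler_vocab_size < 0:
            raise ValueError("filler_vocab_size must be non-negative")
        for p in self.category_prevalence.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("prevalences must lie in [0, 1]")
        for p in self.pair_overlap.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("overlap probabilities must lie in [0, 1]")
        if self.greeting_fraction + self.automated_fraction > 1.0 + 1e-12:
            raise ValueError("greeting_fraction + automated_fraction must be <= 1")
        known = set(self.category_prevalence)
        for a, b in self.pair_overlap:
            if a not in known or b not in known:
                raise ValueError(f"pair_overlap references unknown category ({a},{b})")


@dataclass(frozen=True)
class LabeledCorpus:
    """Generated records plus their planted truth (empty set for excluded lines)."""

    records: tuple[DialogRecord, ...]
    truth_labels: dict[str, frozenset[int]]

    def labeled_truth(self) -> dict[str, LabelSet]:
        return {i: ls for i, ls in self.truth_labels.items() if ls}


def _partner_probability(spec: SyntheticSpec, a: int, b: int) -> float:
    return spec.pair_overlap.get((a, b), spec.pair_overlap.get((b, a), 0.0))


def generate_corpus(spec: SyntheticSpec, lexicon: Lexicon) -> LabeledCorpus:
    """Generate ``spec.n_lines`` patient→HCP records with planted truth labels.

    Labeled content contains at least one keyword from every truth category
    (``keywords_per_line`` draws per category, phrases kept intact) shuffled
    with filler tokens from a vocabulary disjoint from all keywords, so the
    rule-based categorizer recovers the truth exactly when no noise is added.
    Timestamps advance in fixed 1-minute steps.
    """
    spec.validate()
    fallback = lexicon.fallback_code
    for code in spec.category_prevalence:
        cat = lexicon.by_code(code)  # raises KeyError for unknown codes
        if not cat.fallback and not cat.keywords:
            raise ValueError(f"category {code} has no keywords to plant")
    if spec.category_prevalence.get(fallback, 0.0) > 0 and spec.filler_vocab_size == 0:
        raise ValueError("fallback lines need a non-empty filler vocabulary")

    rng = np.random.default_rng(spec.seed)
    greetings = default_greeting_templates()
    automated = default_automated_templates()
    filler = [f"filler{i:04d}" for i in range(spec.filler_vocab_size)]

    codes = sorted(spec.category_prevalence)
    weights = np.array([spec.category_prevalence[c] for c in codes], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("category_prevalence must have positive total mass")
    weights = weights / weights.sum()

    start = datetime(2018, 1, 1, 8, 0)
    records: list[DialogRecord] = []
    truth: dict[str, frozenset[int]] = {}
    for i in range(spec.n_lines):
        identifier = f"msg{i:06d}"
        patient = int(rng.integers(spec.n_patients))
        roll = rng.random()
        if roll < spec.greeting_fraction:
            content = greetings[int(rng.integers(len(greetings)))]
            labels: frozenset[int] = frozenset()
        elif roll < spec.greeting_fraction + spec.automated_fraction:
            content = automated[int(rng.integers(len(automated)))]
            labels = frozenset()
        else:
            base = codes[int(rng.choice(len(codes), p=weights))]
            chosen = {base}
            if base != fallback:
                for other in lexicon.non_fallback_codes:
                    if other != base and rng.random() < _partner_probability(spec, base, other):
                        chosen.add(other)
            labels = frozenset(chosen)
            parts: list[str] = []
            for code in sorted(chosen):
                if code == fallback:
                    continue
                kws = sorted(lexicon.by_code(code).keywords)
                for _ in range(spec.keywords_per_line):
                    parts.append(kws[int(rng.integers(len(kws)))])
            if filler:
                for _ in range(int(rng.integers(1, 4))):
                    parts.append(filler[int(rng.integers(len(filler)))])
            order = rng.permutation(len(parts))
            content = " ".join(parts[j] for j in order)
        records.append(
            DialogRecord(
                identifier=identifier,
                first_name=f"First{patient:03d}",
                last_name=f"Last{patient:03d}",
                timestamp=(start + timedelta(minutes=i)).isoformat(),
                direction=Direction.PATIENT_TO_HCP,
                content=content,
            )
        )
        truth[identifier] = labels
    return LabeledCorpus(records=tuple(records), truth_labels=truth)


def write_log(corpus: LabeledCorpus, destination: str | Path) -> int:
    """Write the corpus log plus a ``<name>.labels.csv`` truth sidecar.

    Returns the number of data rows written to the log. The sidecar has
    columns ``identifier,label_code`` with the canonical ascending digit
    string (empty for greeting/automated lines).
    """
    if not corpus.records:
        raise ValueError("corpus must be non-empty")
    destination = Path(destination)
    n = write_records(corpus.records, destination)
    sidecar = destination.with_suffix(destination.suffix + ".labels.csv")
    with sidecar.open("w", encoding="utf-8", newline="") as fh:
        fh.write("identifier,label_code\n")
        for rec in corpus.records:
            labels = corpus.truth_labels[rec.identifier]
            fh.write(f"{rec.identifier},{label_code(labels) if labels else ''}\n")
    return n


def read_truth_sidecar(source: str | Path) -> dict[str, frozenset[int]]:
    """Read a truth sidecar back into identifier -> label set (possibly empty)."""
    truth: dict[str, frozenset[int]] = {}
    lines = Path(source).read_text(encoding="utf-8").splitlines()
    for line in lines[1:]:
        if not line:
            continue
        identifier, _, code = line.partition(",")
        truth[identifier] = frozenset(int(ch) for ch in code)
    return truth
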