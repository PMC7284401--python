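"""Reading, writing, anonymizing, and subsetting secure-message logs.

The export layout is a 10-field CSV (RFC-4180, UTF-8, header row): identifier,
first_name, last_name, timestamp, direction, content, attachment,
hcp_classification, hcp_responded, hcp_response. Columns are mapped by header
name, not position, with a small alias table for common export variants.
Unknown direction values are hard errors — silently dropping rows would bias
every downstream count. Timestamps are carried as strings: an unparseable
timestamp is a warning, not an error, because time plays no role in the
categorization itself.
"""

from __future__ import annotations

import csv
import enum
import warnings
from dataclasses import dataclass, replace
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence


class Direction(enum.Enum):
    PATIENT_TO_HCP = "patient_to_hcp"
    HCP_TO_PATIENT = "hcp_to_patient"


class HcpClassification(enum.Enum):
    URGENT = "urgent"
    NONURGENT = "nonurgent"
    UNSET = "unset"


#: accepted spellings for each direction value (lower-cased, normalized)
DIRECTION_ALIASES: dict[str, Direction] = {
    "patient_to_hcp": Direction.PATIENT_TO_HCP,
    "patient to hcp": Direction.PATIENT_TO_HCP,
    "patient-to-hcp": Direction.PATIENT_TO_HCP,
    "p2h": Direction.PATIENT_TO_HCP,
    "hcp_to_patient": Direction.HCP_TO_PATIENT,
    "hcp to patient": Direction.HCP_TO_PATIENT,
    "hcp-to-patient": Direction.HCP_TO_PATIENT,
    "h2p": Direction.HCP_TO_PATIENT,
}

#: canonical column order of the 10-field export
FIELD_ORDER = (
    "identifier",
    "first_name",
    "last_name",
    "timestamp",
    "direction",
    "content",
    "attachment",
    "hcp_classification",
    "hcp_responded",
    "hcp_response",
)

#: alternate header spellings mapped to canonical field names
HEADER_ALIASES: dict[str, str] = {
    "id": "identifier",
    "unique_identifier": "identifier",
    "firstname": "first_name",
    "lastname": "last_name",
    "date_time": "timestamp",
    "datetime": "timestamp",
    "message": "content",
    "message_content": "content",
    "hcp_action": "hcp_responded",
    "response": "hcp_response",
}

_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n", ""}


@dataclass(frozen=True)
class DialogRecord:
    """One message with its export metadata; names are nullable after anonymization."""

    identifier: str
    first_name: str | None
    last_name: str | None
    timestamp: str
    direction: Direction
    content: str
    attachment: bool = False
    hcp_classification: HcpClassification = HcpClassification.UNSET
    hcp_responded: bool = False
    hcp_response: str = ""

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("identifier must be non-empty")


def _parse_bool(raw: str, column: str, row: int) -> bool:
    low = raw.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValueError(f"row {row}: cannot parse {column}={raw!r} as a boolean")


def _parse_classification(raw: str, row: int) -> HcpClassification:
    low = raw.strip().lower()
    if low in ("", "unset", "n/a", "na"):
        return HcpClassification.UNSET
    try:
        return HcpClassification(low)
    except ValueError:
        raise ValueError(f"row {row}: unknown hcp_classification {raw!r}") from None


def parse_log(source: str | Path) -> list[DialogRecord]:
    """Parse a 10-field message log into records, preserving row order.

    Headers are matched case-insensitively through the alias table; a missing
    required column or a duplicate identifier is an error. Malformed direction
    values are collected and reported with their row numbers.
    """
    source = Path(source)
    with source.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            raw_header = next(reader)
        except StopIteration:
            raise ValueError(f"{source}: empty file") from None
        header = [HEADER_ALIASES.get(h.strip().lower(), h.strip().lower()) for h in raw_header]
        missing = [f for f in FIELD_ORDER if f not in header]
        if missing:
            raise ValueError(f"{source}: missing required column(s): {', '.join(missing)}")
        index = {f: header.index(f) for f in FIELD_ORDER}

        records: list[DialogRecord] = []
        seen: set[str] = set()
        bad_directions: list[tuple[int, str]] = []
        for row_num, row in enumerate(reader, start=2):
            if not row or all(not c for c in row):
                continue
            get = lambda f: row[index[f]]
            raw_dir = get("direction").strip().lower().replace("→", " to ")
            direction = DIRECTION_ALIASES.get(raw_dir)
            if direction is None:
                bad_directions.append((row_num, get("direction")))
                continue
            identifier = get("identifier")
            if identifier in seen:
                raise ValueError(f"{source}: duplicate identifier {identifier!r} at row {row_num}")
            seen.add(identifier)
            timestamp = get("timestamp")
            try:
                datetime.fromisoformat(timestamp)
            except ValueError:
                warnings.warn(
                    f"{source}: row {row_num}: unparseable timestamp {timestamp!r}; "
                    "raw string retained",
                    stacklevel=2,
                )
            records.append(
                DialogRecord(
                    identifier=identifier,
                    first_name=get("first_name") or None,
                    last_name=get("last_name") or None,
                    timestamp=timestamp,
                    direction=direction,
                    content=get("content"),
                    attachment=_parse_bool(get("attachment"), "attachment", row_num),
                    hcp_classification=_parse_classification(get("hcp_classification"), row_num),
                    hcp_responded=_parse_bool(get("hcp_responded"), "hcp_responded", row_num),
                    hcp_response=get("hcp_response"),
                )
            )
        if bad_directions:
            detail = "; ".join(f"row {r}: {v!r}" for r, v in bad_directions)
            raise ValueError(f"{source}: malformed direction value(s): {detail}")
    return records


def write_records(records: Sequence[DialogRecord], destination: str | Path) -> int:
    """Write records as the canonical 10-column CSV; returns data rows written."""
    destination = Path(destination)
    with destination.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(FIELD_ORDER)
        for rec in records:
            writer.writerow(
                [
                    rec.identifier,
                    rec.first_name or "",
                    rec.last_name or "",
                    rec.timestamp,
                    rec.direction.value,
                    rec.content,
                    "true" if rec.attachment else "false",
                    "" if rec.hcp_classification is HcpClassification.UNSET
                    else rec.hcp_classification.value,
                    "true" if rec.hcp_responded else "false",
                    rec.hcp_response,
                ]
            )
    return len(records)


def anonymize(records: Iterable[DialogRecord]) -> list[DialogRecord]:
    """Null the first/last name fields; everything else — including the unique
    identifier, which downstream analysis keys on — is unchanged. Idempotent."""
    return [replace(rec, first_name=None, last_name=None) for rec in records]


def select_patient_messages(records: Iterable[DialogRecord]) -> list[DialogRecord]:
    """Exactly the patient→HCP records, input order preserved."""
    return [r for r in records if r.direction is Direction.PATIENT_TO_HCP]
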