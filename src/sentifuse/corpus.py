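"""Tweet-record corpora: reading, writing, inclusion filtering and
time-derived annotations.

A corpus is an ordered collection of :class:`TweetRecord`. Records carry a
UTC timestamp from which two derived annotations are computed:

* the study period — ``prepandemic`` is calendar year 2019, ``peripandemic``
  is calendar year 2020, both half-open ``[start, next-start)`` so the
  boundary instant 2020-01-01T00:00Z belongs to the peripandemic year only;
* the clock bucket — ``before_midnight`` covers local hours 13-23
  (1 PM to midnight), ``after_midnight`` covers local hours 0-12
  (midnight to noon; the hour starting at midnight is literally after
  midnight, so it joins the after bucket).

Interchange formats are JSONL (one object per line) and CSV (RFC-4180,
header required), with keys/columns ``id``, ``text``, ``timestamp`` and
optional ``lang``, ``gold_label``.
"""

from __future__ import annotations

import csv
import json
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

from .errors import DuplicateIdError, InputError, SchemaError
from .preprocess import clean_text

__all__ = [
    "SentimentLabel",
    "StudyPeriod",
    "ClockBucket",
    "TweetRecord",
    "Corpus",
    "RowError",
    "FilterResult",
    "read_corpus",
    "write_corpus",
    "filter_inclusion",
    "assign_period",
    "assign_clock_bucket",
    "corpus_to_frame",
]


class SentimentLabel(str, Enum):
    """Three-class sentiment polarity, canonical order negative < neutral < positive."""

    NEGATIVE = "negative"
    NEUTRAL = "neutral"
    POSITIVE = "positive"


#: canonical label order used everywhere (probability vectors, confusion matrices)
LABEL_ORDER = (SentimentLabel.NEGATIVE, SentimentLabel.NEUTRAL, SentimentLabel.POSITIVE)


class StudyPeriod(str, Enum):
    PREPANDEMIC = "prepandemic"
    PERIPANDEMIC = "peripandemic"
    OUT_OF_WINDOW = "out_of_window"


class ClockBucket(str, Enum):
    BEFORE_MIDNIGHT = "before_midnight"  # local hour 13..23
    AFTER_MIDNIGHT = "after_midnight"  # local hour 0..12


_PRE_START = datetime(2019, 1, 1, tzinfo=timezone.utc)
_PERI_START = datetime(2020, 1, 1, tzinfo=timezone.utc)
_PERI_END = datetime(2021, 1, 1, tzinfo=timezone.utc)


@dataclass
class TweetRecord:
    """One post: identity, text, UTC timestamp and derived annotations."""

    id: str
    text: str
    timestamp: datetime
    lang: Optional[str] = None
    gold_label: Optional[SentimentLabel] = None
    clean_text: Optional[str] = None
    period: Optional[StudyPeriod] = None
    bucket: Optional[ClockBucket] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("record id must be nonempty")
        if self.timestamp.tzinfo is None:
            self.timestamp = self.timestamp.replace(tzinfo=timezone.utc)
        else:
            self.timestamp = self.timestamp.astimezone(timezone.utc)

    def annotated(self, tz_offset_minutes: int = 0) -> "TweetRecord":
        """Return a copy with period and clock bucket filled in."""
        return replace(
            self,
            period=assign_period(self.timestamp),
            bucket=assign_clock_bucket(self.timestamp, tz_offset_minutes),
        )


@dataclass
class Corpus:
    """Ordered record collection with a free-text provenance note."""

    records: list[TweetRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TweetRecord]:
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def annotated(self, tz_offset_minutes: int = 0) -> "Corpus":
        return Corpus(
            [r.annotated(tz_offset_minutes) for r in self.records], self.provenance
        )


@dataclass(frozen=True)
class RowError:
    """A malformed input row, kept in the read report rather than dropped."""

    row: int
    id: Optional[str]
    message: str


@dataclass
class FilterResult:
    corpus: Corpus
    excluded: Counter  # reason -> count


def assign_period(timestamp: datetime) -> StudyPeriod:
    """Map an instant to its study period using half-open calendar-year windows."""
    if timestamp.tzinfo is None:
        timestamp = timestamp.replace(tzinfo=timezone.utc)
    if _PRE_START <= timestamp < _PERI_START:
        return StudyPeriod.PREPANDEMIC
    if _PERI_START <= timestamp < _PERI_END:
        return StudyPeriod.PERIPANDEMIC
    return StudyPeriod.OUT_OF_WINDOW


def assign_clock_bucket(
    timestamp: datetime, tz_offset_minutes: int = 0
) -> ClockBucket:
    """Bucket an instant into before-midnight (local 1 PM-midnight) vs
    after-midnight (local midnight-noon) halves of the day.

    ``tz_offset_minutes`` shifts the UTC instant into a fixed local zone
    before the hour is read; offsets beyond +/-14 h are rejected.
    """
    if abs(tz_offset_minutes) > 14 * 60:
        raise InputError(f"tz offset {tz_offset_minutes} min exceeds +/-14 h")
    if timestamp.tzinfo is None:
        timestamp = timestamp.replace(tzinfo=timezone.utc)
    local = timestamp + timedelta(minutes=tz_offset_minutes)
    return (
        ClockBucket.BEFORE_MIDNIGHT if local.hour >= 13 else ClockBucket.AFTER_MIDNIGHT
    )


def _parse_timestamp(raw: str) -> datetime:
    ts = datetime.fromisoformat(str(raw).replace("Z", "+00:00"))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


_REQUIRED = ("id", "text", "timestamp")
_OPTIONAL = ("lang", "gold_label", "clean_text")


def _record_from_mapping(row: dict, rownum: int) -> TweetRecord:
    for key in _REQUIRED:
        if row.get(key) in (None, ""):
            raise SchemaError(f"row {rownum}: missing required field '{key}'")
    gold = row.get("gold_label") or None
    try:
        gold = SentimentLabel(gold) if gold else None
    except ValueError as exc:
        raise InputError(f"row {rownum}: bad gold_label {row['gold_label']!r}") from exc
    try:
        ts = _parse_timestamp(row["timestamp"])
    except ValueError as exc:
        raise InputError(
            f"row {rownum}: unparseable timestamp {row['timestamp']!r}"
        ) from exc
    return TweetRecord(
        id=str(row["id"]),
        text=str(row["text"]),
        timestamp=ts,
        lang=(row.get("lang") or None),
        gold_label=gold,
        clean_text=(row.get("clean_text") or None),
    )


def _iter_rows(path: Path, format: str) -> Iterable[dict]:
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    yield json.loads(line)
    elif format == "csv":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in _REQUIRED if c not in frame.columns]
        if missing:
            raise SchemaError(f"csv missing required column(s): {missing}")
        yield from frame.to_dict("records")
    else:
        raise InputError(f"unknown corpus format {format!r}")


def read_corpus(path, format: str = "jsonl", provenance: str | None = None) -> Corpus:
    """Read a corpus file.

    Malformed rows are collected onto ``corpus.read_errors`` (a list of
    :class:`RowError`), never silently dropped. Structural problems —
    a missing required column, duplicate ids — raise immediately.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    records: list[TweetRecord] = []
    errors: list[RowError] = []
    for rownum, row in enumerate(_iter_rows(path, format), start=1):
        try:
            records.append(_record_from_mapping(row, rownum))
        except (SchemaError, InputError) as exc:
            errors.append(RowError(rownum, str(row.get("id")) or None, str(exc)))
    seen: Counter = Counter(r.id for r in records)
    dupes = [rid for rid, n in seen.items() if n > 1]
    if dupes:
        raise DuplicateIdError(dupes)
    corpus = Corpus(records, provenance or str(path))
    corpus.read_errors = errors  # type: ignore[attr-defined]
    return corpus


def write_corpus(corpus: Corpus, path, format: str = "jsonl") -> None:
    """Write a corpus; a read of the written file reproduces it field-for-field."""
    path = Path(path)
    rows = []
    for r in corpus:
        rows.append(
            {
                "id": r.id,
                "text": r.text,
                "timestamp": r.timestamp.strftime("%Y-%m-%dT%H:%M:%S+00:00"),
                "lang": r.lang or "",
                "gold_label": r.gold_label.value if r.gold_label else "",
                "clean_text": r.clean_text or "",
            }
        )
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row, ensure_ascii=False) + "\n")
    elif format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(_REQUIRED) + list(_OPTIONAL))
            writer.writeheader()
            writer.writerows(rows)
    else:
        raise InputError(f"unknown corpus format {format!r}")


def filter_inclusion(
    corpus: Corpus, keyword: str = "insomnia", lang: str = "en"
) -> FilterResult:
    """Apply the study's inclusion filter: the cleaned, case-folded text must
    contain ``keyword`` as a word-boundary token, and the record's ``lang``
    field (when present) must equal ``lang``.

    Word-boundary matching keeps ``#insomnia`` (the sigil is stripped during
    cleaning) but drops derived words such as ``insomniac``. Returns the kept
    corpus together with exclusion counts keyed by reason
    (``keyword`` / ``lang``).
    """
    if not keyword:
        raise InputError("keyword must be nonempty")
    pattern = re.compile(rf"\b{re.escape(keyword)}\b", re.IGNORECASE)
    kept: list[TweetRecord] = []
    excluded: Counter = Counter()
    for r in corpus:
        if r.lang is not None and r.lang.lower() != lang.lower():
            excluded["lang"] += 1
            continue
        haystack = r.clean_text if r.clean_text is not None else clean_text(r.text)
        if not pattern.search(haystack):
            excluded["keyword"] += 1
            continue
        kept.append(r)
    return FilterResult(Corpus(kept, corpus.provenance), excluded)


def corpus_to_frame(corpus: Corpus, tz_offset_minutes: int = 0) -> pd.DataFrame:
    """Flatten a corpus into the analysis frame used by the statistics layer:
    columns id, label (gold), period, bucket, hour."""
    rows = []
    for r in corpus:
        local = r.timestamp + timedelta(minutes=tz_offset_minutes)
        rows.append(
            {
                "id": r.id,
                "label": r.gold_label.value if r.gold_label else None,
                "period": assign_period(r.timestamp).value,
                "bucket": assign_clock_bucket(r.timestamp, tz_offset_minutes).value,
                "hour": local.hour,
            }
        )
    return pd.DataFrame(
        rows, columns=["id", "label", "period", "bucket", "hour"]
    )
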