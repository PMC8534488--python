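"""Reading, filtering, deduplicating and windowing tweet-like corpora.

The corpus model is deliberately minimal: a record is an id, a UTC
timestamp, a text and an optional language tag.  Every filter is a
record-local predicate, returns a new collection and appends an entry to
the collection's provenance so removal counts stay auditable.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from datetime import date, datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Iterator

__all__ = [
    "TweetRecord",
    "TweetCollection",
    "KeywordFilterSpec",
    "default_keywords",
    "read_tweets",
    "write_tweets",
    "filter_by_keywords",
    "deduplicate",
    "filter_window",
    "filter_language",
]

_RT_PREFIX = re.compile(r"^rt @\S+:?\s*")
_WS = re.compile(r"\s+")


def _parse_timestamp(raw: str) -> datetime:
    """Parse an ISO-8601 timestamp; naive values are taken as UTC."""
    ts = datetime.fromisoformat(raw.replace("Z", "+00:00"))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


@dataclass(frozen=True)
class TweetRecord:
    """One short-text document: id, UTC timestamp, text, optional language."""

    id: str
    created_at: datetime
    text: str
    lang: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be nonempty")
        if not self.text:
            raise ValueError(f"record {self.id!r}: text must be nonempty")
        if self.created_at.tzinfo is None:
            object.__setattr__(
                self, "created_at", self.created_at.replace(tzinfo=timezone.utc)
            )


@dataclass
class TweetCollection:
    """An ordered, id-unique set of records plus filter provenance.

    ``provenance`` is a list of ``(filter_name, n_removed)`` pairs; the
    original input size is always ``len(records) + sum(counts)``.
    """

    records: list[TweetRecord]
    provenance: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate record id {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TweetRecord]:
        return iter(self.records)

    @property
    def doc_ids(self) -> list[str]:
        return [r.id for r in self.records]

    def texts(self) -> list[str]:
        return [r.text for r in self.records]

    def _filtered(self, keep: list[TweetRecord], name: str) -> "TweetCollection":
        removed = len(self.records) - len(keep)
        return TweetCollection(keep, self.provenance + [(name, removed)])


@dataclass(frozen=True)
class KeywordFilterSpec:
    """Lowercase keyword list; plain words, phrases and '#'-hashtags."""

    keywords: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError("keyword list must be nonempty")
        lowered = [k.lower() for k in self.keywords]
        if len(lowered) != len(set(lowered)):
            raise ValueError("keyword list contains duplicates after lowercasing")
        object.__setattr__(self, "keywords", tuple(lowered))


def default_keywords() -> KeywordFilterSpec:
    """The shipped vaccine keyword list (brands, hashtags and generic terms)."""
    text = resources.files("trendmine.data").joinpath("keywords.txt").read_text()
    words = [w.strip() for w in text.splitlines() if w.strip()]
    return KeywordFilterSpec(tuple(words))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_REQUIRED = ("id", "created_at", "text")


def _record_from_mapping(row: dict, lineno: int) -> TweetRecord:
    missing = [k for k in _REQUIRED if not row.get(k)]
    if missing:
        raise ValueError(f"line {lineno}: missing required field(s) {missing}")
    lang = row.get("lang") or None
    return TweetRecord(
        id=str(row["id"]),
        created_at=_parse_timestamp(str(row["created_at"])),
        text=str(row["text"]),
        lang=lang,
    )


def read_tweets(
    path: str | Path,
    format: str | None = None,
    on_error: str = "raise",
) -> TweetCollection:
    """Read a JSONL or CSV corpus into a :class:`TweetCollection`.

    ``format`` is inferred from the suffix when omitted.  ``on_error``
    is ``"raise"`` (default) or ``"skip"``; skipped rows are counted in
    provenance under ``"malformed"``.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown format {format!r}")
    if on_error not in ("raise", "skip"):
        raise ValueError(f"on_error must be 'raise' or 'skip', got {on_error!r}")

    records: list[TweetRecord] = []
    skipped = 0

    def handle(row: dict, lineno: int) -> None:
        nonlocal skipped
        try:
            records.append(_record_from_mapping(row, lineno))
        except (ValueError, KeyError):
            if on_error == "raise":
                raise
            skipped += 1

    with path.open("r", encoding="utf-8", newline="") as fh:
        if format == "jsonl":
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                try:
                    row = json.loads(line)
                except json.JSONDecodeError as exc:
                    if on_error == "raise":
                        raise ValueError(f"line {lineno}: invalid JSON") from exc
                    skipped += 1
                    continue
                handle(row, lineno)
        else:
            for lineno, row in enumerate(csv.DictReader(fh), 2):
                handle(row, lineno)

    provenance = [("malformed", skipped)] if skipped else []
    return TweetCollection(records, provenance)


def write_tweets(col: TweetCollection, path: str | Path) -> None:
    """Write a collection as JSONL in the schema :func:`read_tweets` accepts."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for r in col:
            obj = {
                "id": r.id,
                "created_at": r.created_at.isoformat().replace("+00:00", "Z"),
                "text": r.text,
            }
            if r.lang is not None:
                obj["lang"] = r.lang
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def filter_by_keywords(
    col: TweetCollection, spec: KeywordFilterSpec | None = None
) -> TweetCollection:
    """Retain records whose lowercased text contains at least one keyword.

    Phrases match as contiguous lowercase substrings; hashtags match
    literally including the leading ``#``.
    """
    if spec is None:
        spec = default_keywords()
    keep = [r for r in col if any(k in r.text.lower() for k in spec.keywords)]
    return col._filtered(keep, "keyword")


def normalize_text(text: str) -> str:
    """Duplicate-detection normal form: strip a leading retweet marker,
    collapse whitespace, casefold."""
    t = _WS.sub(" ", text).strip().casefold()
    t = _RT_PREFIX.sub("", t)
    return t.strip()


def deduplicate(col: TweetCollection) -> TweetCollection:
    """Collapse exact duplicates (after normalization) to the earliest record.

    Retweets of a text are duplicates of it.  Ties on the timestamp are
    broken by the smallest id; survivor order follows the input.
    """
    best: dict[str, TweetRecord] = {}
    for r in col:
        key = normalize_text(r.text)
        cur = best.get(key)
        if cur is None or (r.created_at, r.id) < (cur.created_at, cur.id):
            best[key] = r
    survivors = set(id(r) for r in best.values())
    keep = [r for r in col if id(r) in survivors]
    return col._filtered(keep, "duplicate")


def filter_window(col: TweetCollection, start: date, end: date) -> TweetCollection:
    """Retain records whose UTC calendar date lies in [start, end], inclusive."""
    if start > end:
        raise ValueError(f"window start {start} is after end {end}")
    keep = [r for r in col if start <= r.created_at.date() <= end]
    return col._filtered(keep, "window")


def filter_language(
    col: TweetCollection, lang: str = "en", drop_missing: bool = False
) -> TweetCollection:
    """Retain records whose language tag equals ``lang``.

    Records with no tag are retained unless ``drop_missing`` is set; no
    language identification model is applied.
    """
    keep = [
        r
        for r in col
        if (r.lang == lang) or (r.lang is None and not drop_missing)
    ]
    return col._filtered(keep, "language")
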