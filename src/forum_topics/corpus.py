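"""Reading, validating and filtering forum-post collections.

A corpus is the unit of analysis: one forum, one ordered collection of
posts. Files holding several forums are split on load (one topic model is
fitted per source), optionally after merging forum labels — e.g. the two
reddit subforums are conventionally analyzed as a single source.

On-disk formats are deliberately plain: CSV (RFC-4180, header
``post_id,forum_id,timestamp,language,text``) or JSON-lines with the same
keys, timestamps ISO-8601. Timestamps are stored at full date resolution
when available but all analytics downstream truncate to calendar month.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "ForumPost",
    "Corpus",
    "LoadReport",
    "CorpusError",
    "SchemaError",
    "ValidationError",
    "load_corpus",
    "load_corpora",
    "save_corpus",
    "filter_period",
    "parse_month",
    "month_range",
    "month_index",
]

REQUIRED_FIELDS = ("post_id", "forum_id", "timestamp", "language", "text")
DEFAULT_LANGUAGES = frozenset({"de", "en"})
MIN_MONTH = (1990, 1)

Month = tuple[int, int]


class CorpusError(ValueError):
    """Base class for corpus reading/validation problems."""


class SchemaError(CorpusError):
    """A required column or key is missing from the input file."""


class ValidationError(CorpusError):
    """Row-level content violates a corpus invariant."""


# ---------------------------------------------------------------------------
# calendar-month helpers (all analytics are month-resolved)

_MONTH_RE = re.compile(r"^(\d{4})-(\d{2})$")


def parse_month(value: str | Month) -> Month:
    """Parse ``"YYYY-MM"`` (or pass through a ``(year, month)`` pair)."""
    if isinstance(value, tuple):
        y, m = int(value[0]), int(value[1])
    else:
        match = _MONTH_RE.match(str(value).strip())
        if not match:
            raise ValueError(f"not a YYYY-MM month: {value!r}")
        y, m = int(match.group(1)), int(match.group(2))
    if not 1 <= m <= 12:
        raise ValueError(f"month out of range: {value!r}")
    return (y, m)


def month_index(month: Month, start: Month) -> int:
    """Number of months from *start* to *month* (0 for equal)."""
    return (month[0] - start[0]) * 12 + (month[1] - start[1])


def add_months(month: Month, n: int) -> Month:
    total = month[0] * 12 + (month[1] - 1) + n
    return (total // 12, total % 12 + 1)


def month_range(start: Month, end: Month) -> list[Month]:
    """Inclusive list of calendar months from *start* to *end*."""
    if month_index(end, start) < 0:
        raise ValueError(f"start {start} after end {end}")
    return [add_months(start, i) for i in range(month_index(end, start) + 1)]


def parse_timestamp(value: str) -> dt.date:
    """Parse an ISO-8601 date, datetime or bare ``YYYY-MM`` month."""
    text = str(value).strip()
    match = _MONTH_RE.match(text)
    if match:
        return dt.date(int(match.group(1)), int(match.group(2)), 1)
    try:
        return dt.datetime.fromisoformat(text).date()
    except ValueError:
        pass
    return dt.date.fromisoformat(text)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ForumPost:
    """One user contribution: forum label, date, language and raw text."""

    post_id: str
    forum_id: str
    timestamp: dt.date
    language: str
    text: str

    @property
    def month(self) -> Month:
        return (self.timestamp.year, self.timestamp.month)


@dataclass(frozen=True)
class LoadReport:
    """Per-file ingestion accounting: nothing is dropped silently."""

    n_rows: int = 0
    n_loaded: int = 0
    n_malformed: int = 0
    errors: tuple[tuple[int, str], ...] = ()  # (row index, message)


@dataclass(frozen=True)
class Corpus:
    """An ordered, single-forum collection of posts.

    Ordering is stable: by timestamp, then post_id. All posts share
    ``forum_id`` and post ids are unique.
    """

    forum_id: str
    posts: tuple[ForumPost, ...]
    load_report: LoadReport | None = field(default=None, compare=False)

    def __len__(self) -> int:
        return len(self.posts)

    def __iter__(self) -> Iterator[ForumPost]:
        return iter(self.posts)

    def __getitem__(self, i: int) -> ForumPost:
        return self.posts[i]

    @classmethod
    def from_posts(
        cls,
        posts: Iterable[ForumPost],
        forum_id: str | None = None,
        load_report: LoadReport | None = None,
    ) -> "Corpus":
        ordered = tuple(sorted(posts, key=lambda p: (p.timestamp, p.post_id)))
        if forum_id is None:
            if not ordered:
                raise ValidationError("empty corpus needs an explicit forum_id")
            forum_id = ordered[0].forum_id
        stray = sorted({p.forum_id for p in ordered} - {forum_id})
        if stray:
            raise ValidationError(
                f"posts from foreign forums in corpus {forum_id!r}: {stray}"
            )
        dupes = _duplicates(p.post_id for p in ordered)
        if dupes:
            raise ValidationError(f"duplicate post_id(s): {sorted(dupes)}")
        return cls(forum_id=forum_id, posts=ordered, load_report=load_report)

    def span(self) -> tuple[Month, Month]:
        """(first, last) calendar month covered by the corpus."""
        if not self.posts:
            raise ValidationError("empty corpus has no span")
        months = [p.month for p in self.posts]
        return (min(months), max(months))

    def monthly_counts(self) -> dict[Month, int]:
        counts: dict[Month, int] = {}
        for post in self.posts:
            counts[post.month] = counts.get(post.month, 0) + 1
        return counts


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for item in items:
        if item in seen:
            dupes.add(item)
        seen.add(item)
    return dupes


# ---------------------------------------------------------------------------
# reading / writing


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "jsonl"):
            raise ValueError(f"unknown format {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".jsonl", ".ndjson", ".json"):
        return "jsonl"
    return "csv"


def _iter_records(path: Path, fmt: str) -> Iterator[dict]:
    if fmt == "csv":
        with path.open(newline="", encoding="utf-8") as handle:
            reader = csv.DictReader(handle)
            header = reader.fieldnames or []
            missing = [f for f in REQUIRED_FIELDS if f not in header]
            if missing:
                raise SchemaError(f"missing required column(s): {missing}")
            yield from reader
    else:
        with path.open(encoding="utf-8") as handle:
            for line in handle:
                if line.strip():
                    yield json.loads(line)


def _parse_record(
    record: Mapping[str, object],
    row: int,
    languages: frozenset[str],
    max_month: Month,
) -> ForumPost:
    missing = [f for f in REQUIRED_FIELDS if f not in record or record[f] is None]
    if missing and set(missing) != {"text"}:
        raise SchemaError(f"row {row}: missing required field(s): {missing}")
    try:
        timestamp = parse_timestamp(str(record["timestamp"]))
    except ValueError as exc:
        raise ValidationError(f"row {row}: unparseable timestamp: {exc}") from exc
    month = (timestamp.year, timestamp.month)
    if not MIN_MONTH <= month <= max_month:
        raise ValidationError(
            f"row {row}: timestamp {timestamp.isoformat()} outside "
            f"[{MIN_MONTH[0]}-{MIN_MONTH[1]:02d}, {max_month[0]}-{max_month[1]:02d}]"
        )
    language = str(record["language"]).strip().lower()
    if language not in languages:
        raise ValidationError(
            f"row {row}: language {language!r} not in configured set {sorted(languages)}"
        )
    text = record.get("text")
    return ForumPost(
        post_id=str(record["post_id"]),
        forum_id=str(record["forum_id"]),
        timestamp=timestamp,
        language=language,
        text="" if text is None else str(text),
    )


def load_corpora(
    path: str | Path,
    format: str | None = None,
    *,
    languages: Iterable[str] = DEFAULT_LANGUAGES,
    forum_merge: Mapping[str, str] | None = None,
    on_malformed: str = "raise",
) -> dict[str, Corpus]:
    """Load a post file and split it into one :class:`Corpus` per forum.

    ``forum_merge`` maps source forum labels to a shared label (e.g. both
    reddit subforums onto ``"reddit"``). With ``on_malformed="report"``,
    rows failing row-level validation are counted in each corpus's
    :class:`LoadReport` instead of aborting the load; schema errors
    (missing columns) always raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if on_malformed not in ("raise", "report"):
        raise ValueError(f"on_malformed must be 'raise' or 'report', got {on_malformed!r}")
    fmt = _detect_format(path, format)
    langs = frozenset(str(lang).lower() for lang in languages)
    merge = {str(k): str(v) for k, v in (forum_merge or {}).items()}
    today = dt.date.today()
    max_month = (today.year, today.month)

    posts: list[ForumPost] = []
    errors: list[tuple[int, str]] = []
    n_rows = 0
    for row, record in enumerate(_iter_records(path, fmt)):
        n_rows += 1
        try:
            post = _parse_record(record, row, langs, max_month)
        except SchemaError:
            raise
        except ValidationError as exc:
            if on_malformed == "raise":
                raise
            errors.append((row, str(exc)))
            continue
        if post.forum_id in merge:
            post = replace(post, forum_id=merge[post.forum_id])
        posts.append(post)

    dupes = _duplicates(p.post_id for p in posts)
    if dupes:
        raise ValidationError(f"duplicate post_id(s): {sorted(dupes)}")

    by_forum: dict[str, list[ForumPost]] = {}
    for post in posts:
        by_forum.setdefault(post.forum_id, []).append(post)
    report = LoadReport(
        n_rows=n_rows,
        n_loaded=len(posts),
        n_malformed=len(errors),
        errors=tuple(errors),
    )
    return {
        forum: Corpus.from_posts(group, forum_id=forum, load_report=report)
        for forum, group in sorted(by_forum.items())
    }


def load_corpus(
    path: str | Path,
    format: str | None = None,
    *,
    languages: Iterable[str] = DEFAULT_LANGUAGES,
    forum_merge: Mapping[str, str] | None = None,
    on_malformed: str = "raise",
) -> Corpus:
    """Load a single-forum post file (errors if several forums remain)."""
    corpora = load_corpora(
        path,
        format,
        languages=languages,
        forum_merge=forum_merge,
        on_malformed=on_malformed,
    )
    if len(corpora) != 1:
        raise ValidationError(
            f"{path} holds {len(corpora)} forums {sorted(corpora)}; "
            "use load_corpora() or forum_merge to combine them"
        )
    return next(iter(corpora.values()))


def save_corpus(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    """Write a corpus back to CSV or JSON-lines (round-trip safe)."""
    path = Path(path)
    fmt = _detect_format(path, format)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as handle:
            writer = csv.writer(handle)
            writer.writerow(REQUIRED_FIELDS)
            for post in corpus:
                writer.writerow(
                    [post.post_id, post.forum_id, post.timestamp.isoformat(),
                     post.language, post.text]
                )
    else:
        with path.open("w", encoding="utf-8") as handle:
            for post in corpus:
                handle.write(json.dumps(
                    {
                        "post_id": post.post_id,
                        "forum_id": post.forum_id,
                        "timestamp": post.timestamp.isoformat(),
                        "language": post.language,
                        "text": post.text,
                    },
                    ensure_ascii=False,
                ))
                handle.write("\n")


# ---------------------------------------------------------------------------
# filtering


def filter_period(corpus: Corpus, start: str | Month, end: str | Month) -> Corpus:
    """Restrict a corpus to posts with start <= month <= end (inclusive)."""
    start_m, end_m = parse_month(start), parse_month(end)
    if month_index(end_m, start_m) < 0:
        raise ValueError(f"start {start_m} after end {end_m}")
    kept = tuple(p for p in corpus.posts if start_m <= p.month <= end_m)
    return Corpus(forum_id=corpus.forum_id, posts=kept, load_report=corpus.load_report)
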