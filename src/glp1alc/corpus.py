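"""Reading, cleaning and filtering of social-media post corpora.

A raw corpus is a list of :class:`Post` records (one per submission or
comment, with user/subreddit/timestamp metadata).  :func:`preprocess_corpus`
applies the cleaning pipeline used throughout the project: merge the title
into the body, strip URLs/punctuation/case, drop English stopwords, remove
exact duplicates and posts that remain too short to carry a theme.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterable, Sequence

from .stopwords import STOPWORDS

__all__ = [
    "Post",
    "Corpus",
    "IngestReport",
    "RetentionReport",
    "SchemaError",
    "read_posts",
    "write_posts_jsonl",
    "clean_text",
    "preprocess_corpus",
]

REQUIRED_FIELDS = ("id", "user", "subreddit", "created_utc", "title", "body")

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
# tokens are runs of [a-z0-9] possibly joined by internal apostrophes
_TOKEN_RE = re.compile(r"[a-z0-9]+(?:'[a-z0-9]+)*")
_APOSTROPHES = str.maketrans({"’": "'", "‘": "'", "ʼ": "'"})


class SchemaError(ValueError):
    """A required column/key is absent from the input file."""


@dataclass(frozen=True)
class Post:
    id: str
    user: str
    subreddit: str
    timestamp: datetime
    title: str
    body: str


@dataclass
class IngestReport:
    """Row-level outcome of reading a corpus file."""

    n_rows: int = 0
    n_parsed: int = 0
    errors: list[tuple[str, str]] = field(default_factory=list)  # (row id, message)

    @property
    def n_malformed(self) -> int:
        return len(self.errors)


@dataclass
class RetentionReport:
    n_input: int
    n_retained: int
    n_duplicates: int
    n_too_short: int

    def check(self) -> None:
        assert self.n_retained + self.n_duplicates + self.n_too_short == self.n_input


@dataclass
class Corpus:
    """Cleaned corpus: posts plus their token sequences, in parallel order."""

    posts: list[Post]
    cleaned: list[list[str]]
    provenance: dict = field(default_factory=dict)
    report: RetentionReport | None = None

    def __post_init__(self) -> None:
        if len(self.posts) != len(self.cleaned):
            raise ValueError("posts and cleaned token lists must be parallel")

    def __len__(self) -> int:
        return len(self.posts)

    @property
    def texts(self) -> list[str]:
        return [" ".join(toks) for toks in self.cleaned]


def _parse_timestamp(value) -> datetime:
    if isinstance(value, datetime):
        ts = value
    else:
        s = str(value)
        try:
            ts = datetime.fromisoformat(s.replace("Z", "+00:00"))
        except ValueError:
            # epoch seconds are common in Reddit exports
            try:
                ts = datetime.fromtimestamp(float(s), tz=timezone.utc)
            except (ValueError, OverflowError) as exc:
                raise ValueError(f"unparseable timestamp {value!r}") from exc
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def _row_to_post(row: dict) -> Post:
    # an empty title is legitimate (bare comments); every other field,
    # body included, must be present and nonempty
    missing = [k for k in REQUIRED_FIELDS if row.get(k) in (None, "") and k != "title"]
    if row.get("title") is None:
        missing.insert(0, "title")
    if missing:
        raise ValueError(f"missing field(s): {', '.join(missing)}")
    return Post(
        id=str(row["id"]),
        user=str(row["user"]),
        subreddit=str(row["subreddit"]),
        timestamp=_parse_timestamp(row["created_utc"]),
        title=str(row["title"]),
        body=str(row["body"]),
    )


def read_posts(path, format: str | None = None) -> tuple[list[Post], IngestReport]:
    """Read posts from a JSONL or CSV file.

    Malformed rows are skipped but recorded in the returned
    :class:`IngestReport`; a file whose header/keys lack a required field
    entirely raises :class:`SchemaError`.
    """
    path = str(path)
    if format is None:
        format = "csv" if path.endswith(".csv") else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown format {format!r}")

    report = IngestReport()
    posts: list[Post] = []

    if format == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            absent = [k for k in REQUIRED_FIELDS if k not in header]
            if absent:
                raise SchemaError(f"CSV header lacks required column(s): {', '.join(absent)}")
            rows: Iterable[dict] = reader
            _collect(rows, posts, report)
    else:
        with open(path, encoding="utf-8") as fh:
            rows = []
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError:
                    report.n_rows += 1
                    report.errors.append((f"line {lineno}", "invalid JSON"))
                    continue
                rows.append(obj)
            if rows:
                keys = set().union(*(r.keys() for r in rows))
                absent = [k for k in REQUIRED_FIELDS if k not in keys]
                if absent:
                    raise SchemaError(
                        f"JSONL records lack required key(s): {', '.join(absent)}"
                    )
            _collect(rows, posts, report)
    return posts, report


def _collect(rows: Iterable[dict], posts: list[Post], report: IngestReport) -> None:
    for row in rows:
        report.n_rows += 1
        try:
            posts.append(_row_to_post(row))
            report.n_parsed += 1
        except ValueError as exc:
            report.errors.append((str(row.get("id", "?")), str(exc)))


def write_posts_jsonl(posts: Sequence[Post], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in posts:
            fh.write(
                json.dumps(
                    {
                        "id": p.id,
                        "user": p.user,
                        "subreddit": p.subreddit,
                        "created_utc": p.timestamp.isoformat(),
                        "title": p.title,
                        "body": p.body,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def clean_text(title: str, body: str, stopwords: frozenset[str] = STOPWORDS) -> list[str]:
    """Merge title and body into one cleaned token sequence.

    URLs are removed before tokenization; remaining text is lowercased and
    split into runs of ``[a-z0-9]`` (internal apostrophes preserved, so
    ``don't`` survives); stopwords are dropped.  Title tokens precede body
    tokens.  Total function: empty inputs give an empty sequence.
    """
    tokens: list[str] = []
    for part in (title, body):
        text = (part or "").translate(_APOSTROPHES).lower()
        text = _URL_RE.sub(" ", text)
        tokens.extend(t for t in _TOKEN_RE.findall(text) if t not in stopwords)
    return tokens


def preprocess_corpus(
    posts: Sequence[Post],
    min_chars: int = 100,
    stopwords: frozenset[str] = STOPWORDS,
) -> Corpus:
    """Clean a raw post list into a :class:`Corpus`.

    Pipeline order: merge+clean each post; drop exact duplicates of the
    cleaned text (the copy with the earliest timestamp is kept); drop posts
    whose cleaned text, joined by single spaces, is shorter than
    ``min_chars`` characters.  Retained posts keep their input order and a
    :class:`RetentionReport` accounts for every input post.
    """
    cleaned = [clean_text(p.title, p.body, stopwords) for p in posts]

    # duplicate removal: for each distinct cleaned text keep the earliest
    # timestamp (ties resolved by input order)
    keep_idx: dict[str, int] = {}
    for i, toks in enumerate(cleaned):
        key = " ".join(toks)
        j = keep_idx.get(key)
        if j is None or posts[i].timestamp < posts[j].timestamp:
            keep_idx[key] = i
    kept = set(keep_idx.values())

    out_posts: list[Post] = []
    out_cleaned: list[list[str]] = []
    n_dup = 0
    n_short = 0
    for i, (post, toks) in enumerate(zip(posts, cleaned)):
        if i not in kept:
            n_dup += 1
            continue
        if len(" ".join(toks)) < min_chars:
            n_short += 1
            continue
        out_posts.append(post)
        out_cleaned.append(toks)

    report = RetentionReport(
        n_input=len(posts),
        n_retained=len(out_posts),
        n_duplicates=n_dup,
        n_too_short=n_short,
    )
    report.check()
    return Corpus(
        posts=out_posts,
        cleaned=out_cleaned,
        provenance={"min_chars": min_chars},
        report=report,
    )
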