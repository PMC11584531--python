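"""Reading and normalizing social-media post collections.

Posts arrive either as JSON-lines in the Pushshift Reddit submission
schema (``id``, ``created_utc``, ``title``, ``selftext``) or as generic
CSV (``post_id``, ``timestamp``, ``title``, ``body``). Only the
identifier, timestamp, title and body are kept — usernames and every
other field are discarded. Title and body are joined with a single
space and lowercased into the ``text`` field that all downstream
matching and tokenization operate on.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

log = logging.getLogger(__name__)

__all__ = ["Post", "LoadResult", "load_posts", "save_posts", "filter_by_date"]


@dataclass(frozen=True)
class Post:
    """One social-media submission.

    ``text`` is the normalized lowercase concatenation of title and
    body, joined with a single space (empty parts omitted so a missing
    title leaves no leading whitespace).
    """

    post_id: str
    timestamp: int
    title: str
    body: str
    text: str

    @classmethod
    def create(cls, post_id: str, timestamp: int, title: str = "", body: str = "") -> "Post":
        parts = [p for p in (title, body) if p]
        return cls(
            post_id=str(post_id),
            timestamp=int(timestamp),
            title=title,
            body=body,
            text=" ".join(parts).lower(),
        )


class LoadResult(NamedTuple):
    """Posts in file order plus the count of skipped records."""

    posts: list[Post]
    skipped: int


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".jsonl", ".json", ".ndjson"}:
        return "jsonl"
    if suffix in {".csv"}:
        return "csv"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format explicitly")


def load_posts(path, format: str | None = None) -> LoadResult:
    """Load a post collection from JSONL or CSV.

    Records missing a timestamp are skipped with a logged warning and
    counted in the returned ``skipped``. Missing title or body fields
    are treated as empty strings. Records without an identifier get a
    sequential ``p<line>`` id.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in {"jsonl", "csv"}:
        raise ValueError(f"unknown format {fmt!r}")

    posts: list[Post] = []
    skipped = 0

    def add(record: dict, lineno: int, id_key: str, ts_key: str, title_key: str, body_key: str) -> None:
        nonlocal skipped
        ts = record.get(ts_key)
        if ts is None or ts == "":
            log.warning("record %d in %s has no timestamp; skipped", lineno, path.name)
            skipped += 1
            return
        post_id = record.get(id_key) or f"p{lineno}"
        posts.append(
            Post.create(
                post_id=post_id,
                timestamp=int(float(ts)),
                title=str(record.get(title_key) or ""),
                body=str(record.get(body_key) or ""),
            )
        )

    if fmt == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                add(json.loads(line), lineno, "id", "created_utc", "title", "selftext")
    else:
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return LoadResult([], 0)
            for lineno, record in enumerate(reader, start=1):
                add(record, lineno, "post_id", "timestamp", "title", "body")

    ids = [p.post_id for p in posts]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate post ids in {path.name}")
    return LoadResult(posts, skipped)


def save_posts(posts: Iterable[Post], path) -> None:
    """Persist posts as Pushshift-schema JSONL (round-trips with load_posts)."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in posts:
            fh.write(
                json.dumps(
                    {"id": p.post_id, "created_utc": p.timestamp, "title": p.title, "selftext": p.body},
                    ensure_ascii=False,
                )
                + "\n"
            )


def filter_by_date(posts: Sequence[Post], start: int, end: int) -> list[Post]:
    """Posts with start <= timestamp < end (half-open), order preserved."""
    if start > end:
        raise ValueError(f"start ({start}) must not exceed end ({end})")
    return [p for p in posts if start <= p.timestamp < end]
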