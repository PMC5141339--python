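"""Forum-corpus data model and I/O.

A corpus is a flat collection of :class:`Post` records (one forum message
each, with thread / user / timestamp metadata) plus, after annotation, a
derived collection of :class:`Sentence` records carrying POS tags and
stemmed verbs.  Posts are the unit of authorship; threads are retained only
as grouping metadata.  Timestamps are ISO-8601 and normalised to UTC
calendar dates (month resolution is the minimum required downstream; day
resolution is preferred and is what the packaged generator emits).
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from ._text import (
    NOUN_TAGS,
    VERB_TAGS,
    RuleTagger,
    porter_stem,
    split_sentences,
    tokenize,
)

logger = logging.getLogger(__name__)

REQUIRED_FIELDS = ("post_id", "thread_id", "user_id", "timestamp", "text")


@dataclass(frozen=True)
class Post:
    """One forum message."""

    post_id: str
    thread_id: str
    user_id: str
    timestamp: pd.Timestamp
    text: str
    site_id: str = ""

    def to_record(self) -> dict:
        return {
            "post_id": self.post_id,
            "thread_id": self.thread_id,
            "user_id": self.user_id,
            "timestamp": self.timestamp.isoformat(),
            "site_id": self.site_id,
            "text": self.text,
        }


@dataclass(frozen=True)
class Sentence:
    """One sentence of a post, tokenised and annotated.

    ``tokens`` is an ordered list of ``(surface, tag)`` pairs;
    ``verbs_stemmed`` lists ``(token_position, stem)`` for every verb-tagged
    token, stemmed with the package Porter stemmer.
    """

    post_ref: str
    index: int
    tokens: Tuple[Tuple[str, str], ...]
    verbs_stemmed: Tuple[Tuple[int, str], ...]

    @property
    def sent_id(self) -> str:
        return f"{self.post_ref}:{self.index}"

    def surfaces(self) -> Tuple[str, ...]:
        return tuple(tok for tok, _ in self.tokens)


@dataclass
class RejectedRecord:
    """A malformed input record, retained for the ingestion report."""

    line_number: int
    reason: str
    raw: str


@dataclass
class Corpus:
    """Posts plus (after :func:`segment_and_tag`) derived sentences."""

    posts: List[Post] = field(default_factory=list)
    sentences: List[Sentence] = field(default_factory=list)
    rejects: List[RejectedRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.posts)

    @property
    def sites(self) -> List[str]:
        return sorted({p.site_id for p in self.posts})

    def post_index(self) -> Dict[str, Post]:
        return {p.post_id: p for p in self.posts}

    def validate(self) -> None:
        ids = [p.post_id for p in self.posts]
        if len(ids) != len(set(ids)):
            raise ValueError("post_id values are not unique within the corpus")
        known = set(ids)
        for s in self.sentences:
            if s.post_ref not in known:
                raise ValueError(f"sentence references unknown post {s.post_ref!r}")

    def is_annotated(self) -> bool:
        return bool(self.sentences) or not self.posts


class CorpusFormatError(ValueError):
    """Fatal problem with a corpus file (unreadable, wrong header, ...)."""


def _parse_record(record: dict, line_number: int) -> Post:
    for fieldname in REQUIRED_FIELDS:
        if fieldname not in record or record[fieldname] is None or (
            fieldname != "text" and str(record[fieldname]) == ""
        ):
            raise ValueError(f"missing required field {fieldname!r}")
    try:
        ts = pd.Timestamp(str(record["timestamp"]))
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable timestamp {record['timestamp']!r}: {exc}")
    if pd.isna(ts):
        raise ValueError(f"unparseable timestamp {record['timestamp']!r}")
    return Post(
        post_id=str(record["post_id"]),
        thread_id=str(record["thread_id"]),
        user_id=str(record["user_id"]),
        timestamp=ts,
        text=str(record["text"]),
        site_id=str(record.get("site_id", "") or ""),
    )


def read_corpus(path: str | Path, format: Optional[str] = None) -> Corpus:
    """Read a corpus from JSONL (one post object per line) or CSV.

    Malformed records are counted, logged with their line number, and kept
    in ``corpus.rejects``; an unreadable file or a missing header is fatal.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise CorpusFormatError(f"unknown corpus format {format!r}")
    try:
        raw = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise CorpusFormatError(f"cannot read {path}: {exc}") from exc

    corpus = Corpus()
    if format == "jsonl":
        for i, line in enumerate(raw.splitlines(), start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
                if not isinstance(record, dict):
                    raise ValueError("record is not a JSON object")
                corpus.posts.append(_parse_record(record, i))
            except ValueError as exc:
                logger.warning("line %d rejected: %s", i, exc)
                corpus.rejects.append(RejectedRecord(i, str(exc), line))
    else:
        reader = csv.DictReader(io.StringIO(raw))
        if reader.fieldnames is None or not set(REQUIRED_FIELDS) <= set(
            reader.fieldnames
        ):
            raise CorpusFormatError(
                f"CSV header must contain {','.join(REQUIRED_FIELDS)}"
            )
        for i, row in enumerate(reader, start=2):
            try:
                corpus.posts.append(_parse_record(row, i))
            except ValueError as exc:
                logger.warning("line %d rejected: %s", i, exc)
                corpus.rejects.append(RejectedRecord(i, str(exc), json.dumps(row)))
    corpus.validate()
    return corpus


def write_corpus(
    corpus: Corpus, path: str | Path, format: Optional[str] = None
) -> Path:
    """Write posts to JSONL or CSV; the inverse of :func:`read_corpus`."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format == "jsonl":
        lines = [
            json.dumps(p.to_record(), ensure_ascii=False, sort_keys=True)
            for p in corpus.posts
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    elif format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(
                fh,
                fieldnames=["post_id", "thread_id", "user_id", "timestamp",
                            "site_id", "text"],
            )
            writer.writeheader()
            for p in corpus.posts:
                writer.writerow(p.to_record())
    else:
        raise CorpusFormatError(f"unknown corpus format {format!r}")
    return path


def segment_and_tag(corpus: Corpus, annotator=None) -> Corpus:
    """Decompose every post into sentences and annotate them in place.

    ``annotator`` is any object with ``tag(tokens) -> tags`` over a tagset
    distinguishing nouns and verbs (default: :class:`~narraframe._text.RuleTagger`).
    Verb tokens are recorded with their Porter-stemmed base form, so
    "funded" and "funds" both count toward the stem "fund".  A sentence the
    annotator fails on is skipped with a warning; the pipeline continues.
    """
    annotator = annotator or RuleTagger()
    sentences: List[Sentence] = []
    for post in corpus.posts:
        for idx, sent_text in enumerate(split_sentences(post.text)):
            tokens = tokenize(sent_text)
            if not tokens:
                continue
            try:
                tags = annotator.tag(tokens)
                if len(tags) != len(tokens):
                    raise ValueError("annotator returned unequal-length tags")
            except Exception as exc:  # annotator contract violation
                logger.warning(
                    "skipping sentence %s:%d — annotator failed: %s",
                    post.post_id, idx, exc,
                )
                continue
            verbs = tuple(
                (i, porter_stem(tok))
                for i, (tok, tag) in enumerate(zip(tokens, tags))
                if tag in VERB_TAGS
            )
            sentences.append(
                Sentence(
                    post_ref=post.post_id,
                    index=idx,
                    tokens=tuple(zip(tokens, tags)),
                    verbs_stemmed=verbs,
                )
            )
    corpus.sentences = sentences
    return corpus


def write_annotated(corpus: Corpus, path: str | Path) -> Path:
    """Cache an annotated corpus (posts + sentences) as JSONL."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for p in corpus.posts:
            fh.write(json.dumps({"kind": "post", **p.to_record()},
                                ensure_ascii=False, sort_keys=True) + "\n")
        for s in corpus.sentences:
            fh.write(json.dumps({
                "kind": "sentence",
                "post_ref": s.post_ref,
                "index": s.index,
                "tokens": [list(t) for t in s.tokens],
                "verbs_stemmed": [list(v) for v in s.verbs_stemmed],
            }, ensure_ascii=False, sort_keys=True) + "\n")
    return path


def read_annotated(path: str | Path) -> Corpus:
    """Read a corpus cached by :func:`write_annotated`."""
    corpus = Corpus()
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        record = json.loads(line)
        if record.get("kind") == "post":
            corpus.posts.append(_parse_record(record, i))
        elif record.get("kind") == "sentence":
            corpus.sentences.append(Sentence(
                post_ref=record["post_ref"],
                index=record["index"],
                tokens=tuple((t[0], t[1]) for t in record["tokens"]),
                verbs_stemmed=tuple((v[0], v[1]) for v in record["verbs_stemmed"]),
            ))
        else:
            raise CorpusFormatError(f"line {i}: unknown record kind")
    corpus.validate()
    return corpus
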