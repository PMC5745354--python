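"""Readers and configuration for the end-to-end pipeline.

Tweets come in as JSON-lines, one object per line with ``id``,
``created_at`` (ISO-8601 UTC) and ``text`` — the file format the synthetic
generator writes and the shape a Twitter crawl export reduces to. Gold
labels and lexica are two-column CSV. Pipeline configuration is a flat
``key = value`` file.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, fields
from datetime import datetime, timezone
from pathlib import Path

from .normalize import DEFAULT_KEYWORDS


@dataclass
class TweetRecord:
    """One collected post, prior to any processing."""

    id: str
    created_at: datetime
    text: str


def _parse_timestamp(raw: str) -> datetime:
    ts = datetime.fromisoformat(raw.replace("Z", "+00:00"))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def read_tweets(path) -> list[TweetRecord]:
    """Parse a JSONL tweet file, preserving order and rejecting duplicates.

    Raises ValueError naming the offending line for malformed JSON, missing
    fields or duplicate ids.
    """
    records: list[TweetRecord] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"line {lineno}: malformed JSON ({exc})") from exc
            for key in ("id", "created_at", "text"):
                if key not in obj:
                    raise ValueError(f"line {lineno}: missing field {key!r}")
            tid = str(obj["id"])
            if tid in seen:
                raise ValueError(f"line {lineno}: duplicate tweet id {tid!r}")
            seen.add(tid)
            records.append(
                TweetRecord(
                    id=tid,
                    created_at=_parse_timestamp(obj["created_at"]),
                    text=obj["text"],
                )
            )
    return records


def read_labels_csv(path) -> dict[str, str]:
    """Read a gold-label CSV (id,label) into an id -> label mapping."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out[str(row["id"])] = row["label"]
    return out


def read_label_map_csv(path) -> dict[int, str]:
    """Read a topic label map CSV (topic,label); merging is many-to-one."""
    out: dict[int, str] = {}
    with open(path, encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out[int(row["topic"])] = row["label"]
    return out


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs, loadable from a key=value file."""

    keywords: tuple[str, ...] = DEFAULT_KEYWORDS
    stopwords_path: str | None = None
    lexicon_path: str | None = None
    label_map_path: str | None = None
    k: int = 10
    k_grid: tuple[int, ...] = ()
    alpha: float | None = None
    beta: float = 0.1
    n_sweeps: int = 1000
    cutoff: float = 0.1
    seed: int = 0
    months: tuple[str, ...] = ()
    outdir: str = "lynchtweets_out"

    def validate(self) -> None:
        if not 0 < self.cutoff < 1:
            raise ValueError(f"cutoff must be in (0, 1), got {self.cutoff}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        for attr in ("stopwords_path", "lexicon_path", "label_map_path"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{attr} does not exist: {p}")


_LIST_KEYS = {"keywords", "months"}
_INT_LIST_KEYS = {"k_grid"}
_INT_KEYS = {"k", "n_sweeps", "seed"}
_FLOAT_KEYS = {"alpha", "beta", "cutoff"}


def load_config(path) -> PipelineConfig:
    """Parse a flat key = value config file ('#' starts a comment line)."""
    known = {f.name for f in fields(PipelineConfig)}
    kwargs = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in known:
                raise ValueError(f"line {lineno}: unknown config key {key!r}")
            if key in _LIST_KEYS:
                kwargs[key] = tuple(v.strip() for v in value.split(",") if v.strip())
            elif key in _INT_LIST_KEYS:
                kwargs[key] = tuple(int(v) for v in value.split(",") if v.strip())
            elif key in _INT_KEYS:
                kwargs[key] = int(value)
            elif key in _FLOAT_KEYS:
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
    return PipelineConfig(**kwargs)
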