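"""Three-class polarity labeling and per-topic sentiment summaries.

The pipeline treats the sentiment stage as a pluggable interface: any
callable mapping a normalized tweet to one of ``positive`` / ``negative`` /
``neutral`` slots in. The reference implementation is a lexicon baseline in
the Linguistic-Inquiry-and-Word-Count family: sum word polarities over the
tweet's tokens and take the sign. Negation is deliberately not handled.

Polarity labels map to numeric scores +1 / -1 / 0, and a group of tweets is
summarized by the normalized score (pos - neg) / total, in [-1, 1].
"""

from __future__ import annotations

import csv
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

from .normalize import NormalizedTweet

POSITIVE = "positive"
NEGATIVE = "negative"
NEUTRAL = "neutral"
SENTIMENT_LABELS = (POSITIVE, NEGATIVE, NEUTRAL)

#: label <-> numeric score bijection
SENTIMENT_SCORES = {POSITIVE: 1, NEGATIVE: -1, NEUTRAL: 0}


def load_lexicon(path=None) -> dict[str, int]:
    """Load a word->polarity lexicon from a two-column CSV (word,polarity).

    Polarity must be +1 or -1; a word mapped to both polarities is an error.
    Default is the small bundled lexicon.
    """
    if path is None:
        source = resources.files("lynchtweets.data").joinpath("lexicon.csv")
        lines = source.read_text(encoding="utf-8").splitlines()
    else:
        with open(path, encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    lexicon: dict[str, int] = {}
    for row in csv.DictReader(lines):
        word = row["word"].strip().lower()
        pol = int(row["polarity"])
        if pol not in (1, -1):
            raise ValueError(f"polarity for {word!r} must be +1 or -1, got {pol}")
        if word in lexicon and lexicon[word] != pol:
            raise ValueError(f"word {word!r} mapped to both polarities")
        lexicon[word] = pol
    return lexicon


def classify_sentiment(
    tweet: NormalizedTweet, lexicon: Mapping[str, int]
) -> str:
    """Sign of the summed lexicon polarities over the tweet's tokens."""
    total = sum(lexicon.get(tok, 0) for tok in tweet.tokens)
    if total > 0:
        return POSITIVE
    if total < 0:
        return NEGATIVE
    return NEUTRAL


def sentiment_score(pos: int, neg: int, neu: int) -> float | None:
    """Normalized sentiment (pos - neg) / (pos + neg + neu), in [-1, 1].

    Returns None (missing) when there are no tweets, never 0: an empty
    month is not a neutral month.
    """
    if min(pos, neg, neu) < 0:
        raise ValueError("counts must be nonnegative")
    total = pos + neg + neu
    if total == 0:
        return None
    return (pos - neg) / total


def _pct(count: int, total: int) -> float:
    """Percentage rounded half-up to 2 decimals (table display convention)."""
    if total == 0:
        return 0.0
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def sentiment_distribution(
    labels: Sequence[str], topics: Sequence[str | None]
) -> pd.DataFrame:
    """Counts and row percentages of polarity by topic, plus an overall row.

    Output columns: positive/negative/neutral counts and *_pct percentages
    (rounded half-up to 2 decimals); one row per topic in first-appearance
    order, tweets without a topic grouped under "none", and a final
    "overall" row over all tweets.
    """
    if len(labels) != len(topics):
        raise ValueError("labels and topics must align")
    rows: dict[str, dict[str, int]] = {}
    for lab, top in zip(labels, topics):
        key = top if top is not None else "none"
        counts = rows.setdefault(key, {s: 0 for s in SENTIMENT_LABELS})
        counts[lab] += 1
    overall = {s: sum(r[s] for r in rows.values()) for s in SENTIMENT_LABELS}
    rows["overall"] = overall
    records = []
    for topic, counts in rows.items():
        total = sum(counts.values())
        rec = {"topic": topic}
        for s in SENTIMENT_LABELS:
            rec[s] = counts[s]
            rec[f"{s}_pct"] = _pct(counts[s], total)
        records.append(rec)
    return pd.DataFrame(records).set_index("topic")
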