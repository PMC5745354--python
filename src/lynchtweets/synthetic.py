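"""Synthetic tweet-corpus generator with planted ground truth.

The original Lynch-syndrome tweet collection cannot be redistributed, so
every stage of the pipeline is exercised on corpora drawn from the same
generative structure the analysis assumes:

* topic content is a Dirichlet-multinomial mixture — a planted K x V
  topic-word matrix (rows ~ Dirichlet(topic_word_conc)) and per-tweet topic
  mixtures (~ Dirichlet(doc_topic_conc));
* each tweet belongs to one of three classes (irrelevant / promotional /
  layperson) with class-conditional link frequency: promotional tweets
  almost always carry a ``https://t.co/...`` URL, laypeople mostly do not;
* irrelevant tweets contain the distractor keyword "willie"/"willy" with
  high probability (posts about the person Willy Lynch);
* layperson tweets carry a planted polarity, realized by injecting a
  matching lexicon word;
* tweet volume is uniform over the study months except one awareness-event
  month scaled by a multiplier (emulating the March awareness spike).

Vocabulary words are synthetic strings "w0001"... so they can never collide
with placeholder tokens, distractor keywords, collection keywords or
lexicon words, which keeps downstream assertions exact.
"""

from __future__ import annotations

import calendar
import csv
import json
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone
from typing import Sequence

import numpy as np

from .sentiment import NEGATIVE, NEUTRAL, POSITIVE, load_lexicon

DEFAULT_MONTHS = (
    "2016-10", "2016-11", "2016-12", "2017-01", "2017-02", "2017-03",
    "2017-04", "2017-05", "2017-06", "2017-07", "2017-08",
)

_URL_ALPHABET = list("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789")


@dataclass
class SyntheticConfig:
    """Generative parameters of a synthetic tweet corpus.

    Defaults reflect the study conditions: eleven months from October 2016
    to August 2017 with the awareness-event spike in March 2017, class
    proportions matching the observed funnel (about 18.6% irrelevant and
    18.6% layperson among collected English tweets), an 88% no-link rate
    for laypeople (url_prob_layperson=0.12), a 96% distractor rate among
    irrelevant tweets, and layperson polarity proportions matching the
    observed overall sentiment distribution.
    """

    n_tweets: int = 2000
    months: tuple[str, ...] = DEFAULT_MONTHS
    vocab_size: int = 200
    n_topics: int = 5
    doc_topic_conc: float = 0.3
    topic_word_conc: float = 0.05
    tweet_len_mean: float = 12.0
    class_probs: tuple[float, float, float] = (0.186, 0.628, 0.186)
    url_prob_promotional: float = 0.95
    url_prob_layperson: float = 0.12
    distractor_prob: float = 0.96
    hashtag_prob: float = 0.7
    event_month: int = 5              # index into months (2017-03 by default)
    event_multiplier: float = 3.0
    sentiment_probs: tuple[float, float, float] = (0.184, 0.035, 0.781)
    lexicon_inject_rate: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        if self.n_tweets < 0:
            raise ValueError("n_tweets must be >= 0")
        if not self.months:
            raise ValueError("months must be nonempty")
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        if self.vocab_size <= self.n_topics:
            raise ValueError("vocab_size must exceed n_topics")
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        if abs(sum(self.sentiment_probs) - 1.0) > 1e-9:
            raise ValueError("sentiment_probs must sum to 1")
        for name in (
            "url_prob_promotional", "url_prob_layperson", "distractor_prob",
            "hashtag_prob", "lexicon_inject_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(p < 0 or p > 1 for p in self.class_probs):
            raise ValueError("class_probs entries must be in [0, 1]")
        if any(p < 0 or p > 1 for p in self.sentiment_probs):
            raise ValueError("sentiment_probs entries must be in [0, 1]")
        if not 0 <= self.event_month < len(self.months):
            raise ValueError("event_month must index into months")
        if self.event_multiplier < 1.0:
            raise ValueError("event_multiplier must be >= 1")
        if self.doc_topic_conc <= 0 or self.topic_word_conc <= 0:
            raise ValueError("Dirichlet concentrations must be positive")
        if self.tweet_len_mean <= 0:
            raise ValueError("tweet_len_mean must be positive")


@dataclass
class SyntheticTweet:
    id: str
    created_at: datetime
    text: str


@dataclass
class SyntheticTruth:
    """Planted parameters and per-tweet ground-truth labels."""

    vocab: list[str]
    true_topic_word: np.ndarray            # K x V
    true_doc_topic: np.ndarray             # N x K
    true_class: list[str]
    true_sentiment: list[str | None]       # layperson tweets only, else None
    true_month: list[str]


def event_volume_profile(config: SyntheticConfig) -> np.ndarray:
    """Expected tweet count per month: uniform except the event month.

    The event month's weight is scaled by ``event_multiplier``; the profile
    sums to ``n_tweets`` exactly (up to float rounding).
    """
    if not config.months:
        raise ValueError("months must be nonempty")
    if not 0 <= config.event_month < len(config.months):
        raise ValueError("event_month must index into months")
    weights = np.ones(len(config.months))
    weights[config.event_month] = config.event_multiplier
    return config.n_tweets * weights / weights.sum()


def _random_timestamp(rng: np.random.Generator, month: str) -> datetime:
    year, mon = int(month[:4]), int(month[5:7])
    n_days = calendar.monthrange(year, mon)[1]
    day = int(rng.integers(1, n_days + 1))
    sec = int(rng.integers(0, 86400))
    return datetime(year, mon, day, tzinfo=timezone.utc) + timedelta(seconds=sec)


def generate_corpus(
    config: SyntheticConfig,
    lexicon: dict[str, int] | None = None,
) -> tuple[list[SyntheticTweet], SyntheticTruth]:
    """Draw a corpus and its ground truth; bit-reproducible for a fixed seed.

    One RNG stream drives the whole draw, consumed in a fixed order:
    planted topic-word matrix, then per-tweet month / class / topic mixture /
    length / token draws / decorations (hashtag or keyword phrase, URL,
    distractor, sentiment word, timestamp).
    """
    config.validate()
    if lexicon is None:
        lexicon = load_lexicon()
    pos_words = sorted(w for w, p in lexicon.items() if p > 0)
    neg_words = sorted(w for w, p in lexicon.items() if p < 0)
    if not pos_words or not neg_words:
        raise ValueError("lexicon must contain both polarities")

    rng = np.random.default_rng(config.seed)
    K, V = config.n_topics, config.vocab_size
    vocab = [f"w{i:04d}" for i in range(V)]
    phi = rng.dirichlet(np.full(V, config.topic_word_conc), size=K)

    month_weights = event_volume_profile(config)
    month_probs = month_weights / month_weights.sum() if config.n_tweets else None

    tweets: list[SyntheticTweet] = []
    classes: list[str] = []
    sentiments: list[str | None] = []
    months_out: list[str] = []
    thetas = np.zeros((config.n_tweets, K))
    class_names = ("irrelevant", "promotional", "layperson")
    sent_names = (POSITIVE, NEGATIVE, NEUTRAL)

    for i in range(config.n_tweets):
        month = config.months[rng.choice(len(config.months), p=month_probs)]
        cls = class_names[rng.choice(3, p=config.class_probs)]
        theta = rng.dirichlet(np.full(K, config.doc_topic_conc))
        thetas[i] = theta
        length = max(3, int(rng.poisson(config.tweet_len_mean)))
        z = rng.choice(K, size=length, p=theta)
        words = [vocab[rng.choice(V, p=phi[k])] for k in z]

        parts: list[str] = []
        if rng.random() < config.hashtag_prob:
            parts.append("#lynchsyndrome")
        else:
            parts.append("lynch syndrome")
        parts.extend(words)

        if cls == "irrelevant":
            if rng.random() < config.distractor_prob:
                parts.append("willie" if rng.random() < 0.5 else "willy")
            sent = None
        elif cls == "promotional":
            sent = None
        else:
            sent = sent_names[rng.choice(3, p=config.sentiment_probs)]
            if sent != NEUTRAL and rng.random() < config.lexicon_inject_rate:
                pool = pos_words if sent == POSITIVE else neg_words
                parts.append(pool[rng.choice(len(pool))])

        url_prob = {
            "irrelevant": 0.0,
            "promotional": config.url_prob_promotional,
            "layperson": config.url_prob_layperson,
        }[cls]
        if rng.random() < url_prob:
            suffix = "".join(
                _URL_ALPHABET[j] for j in rng.choice(len(_URL_ALPHABET), size=10)
            )
            parts.append(f"https://t.co/{suffix}")

        ts = _random_timestamp(rng, month)
        tweets.append(
            SyntheticTweet(id=f"t{i:06d}", created_at=ts, text=" ".join(parts))
        )
        classes.append(cls)
        sentiments.append(sent)
        months_out.append(month)

    truth = SyntheticTruth(
        vocab=vocab,
        true_topic_word=phi,
        true_doc_topic=thetas,
        true_class=classes,
        true_sentiment=sentiments,
        true_month=months_out,
    )
    return tweets, truth


def planted_recovery_tv(model, truth: SyntheticTruth) -> float:
    """Mean total-variation distance between estimated and planted topics.

    Restricts the fitted topic-word matrix to the planted vocabulary
    columns (renormalizing rows), pairs topics optimally by TV distance,
    and returns the mean matched distance. Words never observed get zero
    probability.
    """
    from .topics import match_topics

    col = {w: i for i, w in enumerate(truth.vocab)}
    phi_est = np.zeros((model.phi.shape[0], len(truth.vocab)))
    for j, w in enumerate(model.vocab):
        if w in col:
            phi_est[:, col[w]] = model.phi[:, j]
    sums = phi_est.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    phi_est = phi_est / sums
    _, tv = match_topics(phi_est, truth.true_topic_word)
    return tv


def write_tweets_jsonl(tweets: Sequence[SyntheticTweet], path) -> None:
    """Write tweets as JSON-lines: {"id", "created_at" ISO-8601 UTC, "text"}."""
    with open(path, "w", encoding="utf-8") as fh:
        for tw in tweets:
            fh.write(json.dumps({
                "id": tw.id,
                "created_at": tw.created_at.strftime("%Y-%m-%dT%H:%M:%SZ"),
                "text": tw.text,
            }) + "\n")


def write_truth_csv(truth: SyntheticTruth, tweets: Sequence[SyntheticTweet], path) -> None:
    """Write per-tweet ground-truth labels as CSV (id,class,sentiment,month)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "class", "sentiment", "month"])
        for tw, cls, sent, month in zip(
            tweets, truth.true_class, truth.true_sentiment, truth.true_month
        ):
            writer.writerow([tw.id, cls, sent or "", month])
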