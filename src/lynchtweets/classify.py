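"""Rule-based tweet categorization and evaluation statistics.

Tweets are partitioned into three classes by two cascading rules applied to
normalized tokens:

1. *relevance*: a tweet is ``irrelevant`` iff it contains the token
   ``willie`` or ``willy`` (posts about the person Willy Lynch that match
   the collection keywords by accident);
2. *source*: a relevant tweet is ``promotional`` iff it carries a link
   (the ``<url>`` placeholder), otherwise it is a ``layperson`` discussion.

The module also provides the support-weighted precision/recall/F evaluation
used to compare classifiers against a gold standard, and Cohen's kappa for
inter-annotator agreement.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .normalize import NormalizedTweet

IRRELEVANT = "irrelevant"
PROMOTIONAL = "promotional"
LAYPERSON = "layperson"
CLASS_LABELS = (IRRELEVANT, PROMOTIONAL, LAYPERSON)

DISTRACTOR_KEYWORDS = frozenset({"willie", "willy"})


def classify_relevance(tweet: NormalizedTweet) -> str:
    """``irrelevant`` iff any token equals "willie" or "willy", else ``relevant``."""
    if any(tok in DISTRACTOR_KEYWORDS for tok in tweet.tokens):
        return IRRELEVANT
    return "relevant"


def classify_source(tweet: NormalizedTweet) -> str:
    """``promotional`` iff the tokens contain the ``<url>`` placeholder."""
    return PROMOTIONAL if "<url>" in tweet.tokens else LAYPERSON


def classify_tweet(tweet: NormalizedTweet) -> str:
    """Full two-stage classification into one of the three classes."""
    if classify_relevance(tweet) == IRRELEVANT:
        return IRRELEVANT
    return classify_source(tweet)


@dataclass
class EvalReport:
    """Per-class and support-weighted precision/recall/F for one task.

    ``per_class`` maps each label to a ``(precision, recall, f1)`` triple
    computed one-vs-rest; ``weighted`` aggregates them with weights equal to
    the gold-class frequencies (weighted F is the support-weighted mean of
    per-class F, the convention of standard metrics libraries).
    """

    per_class: dict[str, tuple[float, float, float]]
    support: dict[str, int]
    weighted: tuple[float, float, float]


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def evaluate_classifier(
    gold: Sequence[str], predicted: Sequence[str]
) -> EvalReport:
    """Support-weighted one-vs-rest precision/recall/F against a gold standard."""
    if len(gold) != len(predicted):
        raise ValueError(
            f"length mismatch: {len(gold)} gold vs {len(predicted)} predicted"
        )
    if not gold:
        raise ValueError("empty label sequences")
    labels = sorted(set(gold) | set(predicted))
    support = Counter(gold)
    per_class: dict[str, tuple[float, float, float]] = {}
    for lab in labels:
        tp = sum(1 for g, p in zip(gold, predicted) if g == lab and p == lab)
        fp = sum(1 for g, p in zip(gold, predicted) if g != lab and p == lab)
        fn = sum(1 for g, p in zip(gold, predicted) if g == lab and p != lab)
        per_class[lab] = _prf(tp, fp, fn)
    n = len(gold)
    weighted = tuple(
        sum(support[lab] / n * per_class[lab][i] for lab in labels)
        for i in range(3)
    )
    return EvalReport(
        per_class=per_class,
        support={lab: support[lab] for lab in labels},
        weighted=weighted,  # type: ignore[arg-type]
    )


def cohen_kappa(labels1: Sequence[str], labels2: Sequence[str]) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e).

    Chance agreement p_e comes from the product of the two annotators'
    marginal label frequencies. Returns 1.0 when both observed and chance
    agreement are perfect (a single shared label).
    """
    if len(labels1) != len(labels2):
        raise ValueError(
            f"length mismatch: {len(labels1)} vs {len(labels2)}"
        )
    if not labels1:
        raise ValueError("empty label sequences")
    n = len(labels1)
    p_o = sum(1 for a, b in zip(labels1, labels2) if a == b) / n
    m1, m2 = Counter(labels1), Counter(labels2)
    p_e = sum(m1[lab] / n * m2[lab] / n for lab in set(m1) | set(m2))
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1 - p_e)
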