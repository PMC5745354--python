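"""Tweet text normalization.

Raw tweet text is reduced to a lowercase whitespace token stream in which
platform artifacts are abstracted into placeholder tokens:

* hashtags ``#Phrase`` become the pair ``<hashtag>`` + lowercased phrase
  (the phrase is kept as a single token, no camel-case splitting);
* user mentions ``@name`` become ``<user>``;
* web addresses become ``<url>``;
* runs of emoji codepoints become ``<emoji>``.

A second pass (:func:`prepare_for_lda`) strips placeholders, stop words and
very short tokens and applies an optional lemma mapping, producing the token
stream that topic modeling consumes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

PLACEHOLDERS = frozenset({"<hashtag>", "<user>", "<url>", "<emoji>"})

#: Keyword phrases used to collect the corpus; matching is case-insensitive
#: substring search on the raw text.
DEFAULT_KEYWORDS = (
    "lynch syndrome",
    "#lynchsyndrome",
    "lynchsyndrome",
    "#lynch_syndrome",
)

_URL_RE = re.compile(r"https?://\S+", re.IGNORECASE)
_MENTION_RE = re.compile(r"@\w+")
_HASHTAG_RE = re.compile(r"#(\w+)")
# Standard emoji blocks: misc symbols, dingbats, emoticons, transport,
# supplemental symbols, flags, plus variation selector 16.
_EMOJI_RE = re.compile(
    "["
    "☀-➿"
    "️"
    "\U0001f1e6-\U0001f1ff"
    "\U0001f300-\U0001f5ff"
    "\U0001f600-\U0001f64f"
    "\U0001f680-\U0001f6ff"
    "\U0001f900-\U0001f9ff"
    "\U0001fa70-\U0001faff"
    "]+"
)


@dataclass
class NormalizedTweet:
    """A tweet after placeholder substitution and LDA token filtering."""

    id: str
    tokens: list[str]
    lda_tokens: list[str] = field(default_factory=list)


def keyword_match(text: str, keywords: Sequence[str] = DEFAULT_KEYWORDS) -> bool:
    """True iff any keyword occurs case-insensitively as a substring of *text*."""
    if not keywords:
        raise ValueError("keywords must be nonempty")
    lowered = text.lower()
    return any(k.lower() in lowered for k in keywords)


def substitute_placeholders(text: str) -> list[str]:
    """Tokenize *text*, replacing hashtags, mentions, URLs and emoji.

    Idempotent: placeholder tokens contain none of the trigger characters,
    so a second application is the identity.
    """
    text = _URL_RE.sub(" <url> ", text)
    text = _MENTION_RE.sub(" <user> ", text)
    text = _HASHTAG_RE.sub(lambda m: f" <hashtag> {m.group(1)} ", text)
    text = _EMOJI_RE.sub(" <emoji> ", text)
    tokens = []
    for tok in text.split():
        tokens.append(tok if tok in PLACEHOLDERS else tok.lower())
    return tokens


def load_stopwords(path=None) -> frozenset[str]:
    """Load a stop-word list, one word per line; default is the bundled list."""
    if path is None:
        source = resources.files("lynchtweets.data").joinpath("stopwords.txt")
        raw = source.read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            raw = fh.read()
    return frozenset(w.strip() for w in raw.splitlines() if w.strip())


def prepare_for_lda(
    tokens: Iterable[str],
    stopwords: frozenset[str] | set[str] | None = None,
    lemmatizer: Mapping[str, str] | None = None,
) -> list[str]:
    """Filter a placeholder-substituted token stream for topic modeling.

    Removes placeholder tokens, stop words and tokens shorter than two
    characters, then maps each survivor through *lemmatizer* (identity for
    words it does not contain).
    """
    if stopwords is None:
        stopwords = load_stopwords()
    lemma = lemmatizer or {}
    out = []
    for tok in tokens:
        if tok in PLACEHOLDERS or tok in stopwords or len(tok) < 2:
            continue
        out.append(lemma.get(tok, tok))
    return out


def normalize_tweet(
    tweet_id: str,
    text: str,
    stopwords: frozenset[str] | set[str] | None = None,
    lemmatizer: Mapping[str, str] | None = None,
) -> NormalizedTweet:
    """Full normalization of one tweet: substitution plus LDA filtering."""
    tokens = substitute_placeholders(text)
    return NormalizedTweet(
        id=tweet_id,
        tokens=tokens,
        lda_tokens=prepare_for_lda(tokens, stopwords, lemmatizer),
    )
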