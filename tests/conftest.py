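import pytest

from lynchtweets.classify import classify_tweet
from lynchtweets.normalize import DEFAULT_KEYWORDS, load_stopwords, normalize_tweet
from lynchtweets.pipeline import keyword_stop_tokens
from lynchtweets.synthetic import SyntheticConfig, generate_corpus
from lynchtweets.topics import Corpus


@pytest.fixture(scope="session")
def lda_stopwords():
    """Default stop list plus collection-keyword tokens, as the pipeline uses."""
    return load_stopwords() | keyword_stop_tokens(DEFAULT_KEYWORDS)


@pytest.fixture(scope="session")
def small_corpus(lda_stopwords):
    """A small well-separated synthetic corpus, normalized and LDA-ready."""
    config = SyntheticConfig(
        n_tweets=400, n_topics=3, vocab_size=60,
        topic_word_conc=0.01, doc_topic_conc=0.2, seed=11,
    )
    tweets, truth = generate_corpus(config)
    normalized = [
        normalize_tweet(t.id, t.text, stopwords=lda_stopwords) for t in tweets
    ]
    docs, ids = [], []
    for nt in normalized:
        if nt.lda_tokens and classify_tweet(nt) != "irrelevant":
            docs.append(nt.lda_tokens)
            ids.append(nt.id)
    return Corpus(docs, doc_ids=ids), truth, config
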