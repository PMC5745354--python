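"""End-to-end driver: normalize -> classify -> topics -> sentiment -> trends.

The run mirrors the four-step surveillance workflow: keyword-filter and
normalize the collected tweets, partition them into irrelevant /
promotional / layperson by the two cascading rules, fit LDA on the relevant
tweets, threshold topic probabilities, label layperson sentiment with the
configured lexicon, and aggregate everything into the monthly panel and its
derived reports. All randomness flows from the single configured seed, so a
run is idempotent: same seed and inputs, byte-identical outputs.

The funnel counts (collected -> keyword-matched -> relevant ->
promotional / layperson) are the primary sanity surface and are logged and
written to the run manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classify import IRRELEVANT, LAYPERSON, PROMOTIONAL, classify_tweet
from .io import PipelineConfig, TweetRecord, read_label_map_csv
from .normalize import keyword_match, load_stopwords, normalize_tweet
from .sentiment import classify_sentiment, load_lexicon, sentiment_distribution
from .topics import Corpus, assign_topics, fit_lda, select_k, top_words
from .trends import (
    build_panel,
    correlation_table,
    format_p,
    month_key,
    sentiment_trajectory,
    topic_volume_ranking,
)

logger = logging.getLogger("lynchtweets")


def proportion_report(numerator: int, denominator: int) -> str:
    """Render "NN.NN% (num/den)" with half-up rounding and separators."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be between 0 and denominator")
    pct = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return f"{pct}% ({numerator:,}/{denominator:,})"


@dataclass
class RunManifest:
    """Funnel sizes and provenance of one pipeline run."""

    config: dict
    n_collected: int
    n_keyword_matched: int
    n_relevant: int
    n_promotional: int
    n_layperson: int
    version: str
    seed: int

    def __post_init__(self) -> None:
        chain = (self.n_collected, self.n_keyword_matched, self.n_relevant)
        if any(a < b for a, b in zip(chain, chain[1:])):
            raise ValueError(f"funnel sizes must be non-increasing: {chain}")
        if self.n_promotional + self.n_layperson != self.n_relevant:
            raise ValueError("promotional + layperson must equal relevant")


def keyword_stop_tokens(keywords: Sequence[str]) -> set[str]:
    """Tokens the collection keywords reduce to after normalization.

    Every collected tweet contains a keyword, so these tokens appear in
    nearly every document and carry no topical signal; they are removed
    before topic modeling.
    """
    toks: set[str] = set()
    for kw in keywords:
        for part in kw.lower().replace("#", " ").replace("_", " ").split():
            toks.add(part)
        toks.add(kw.lower().lstrip("#").replace("_", ""))
    return toks


def run_pipeline(
    config: PipelineConfig, tweets: Sequence[TweetRecord]
) -> RunManifest:
    """Execute the full workflow and write all reports under config.outdir."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stopwords = load_stopwords(config.stopwords_path)
    lda_stop = set(stopwords) | keyword_stop_tokens(config.keywords)
    lexicon = load_lexicon(config.lexicon_path)
    label_map = (
        read_label_map_csv(config.label_map_path)
        if config.label_map_path
        else None
    )

    n_collected = len(tweets)
    matched = [tw for tw in tweets if keyword_match(tw.text, config.keywords)]
    logger.info("keyword filter: %d in, %d matched", n_collected, len(matched))

    normalized = [
        normalize_tweet(tw.id, tw.text, stopwords=lda_stop) for tw in matched
    ]
    labels = [classify_tweet(nt) for nt in normalized]
    n_relevant = sum(1 for lab in labels if lab != IRRELEVANT)
    n_promo = sum(1 for lab in labels if lab == PROMOTIONAL)
    n_lay = sum(1 for lab in labels if lab == LAYPERSON)
    logger.info(
        "classification: %d relevant (%d promotional, %d layperson)",
        n_relevant, n_promo, n_lay,
    )

    relevant_idx = [i for i, lab in enumerate(labels) if lab != IRRELEVANT]
    docs = [normalized[i].lda_tokens for i in relevant_idx]
    doc_ids = [normalized[i].id for i in relevant_idx]
    nonempty = [j for j, d in enumerate(docs) if d]

    primary_topic: dict[str, str | None] = {}
    if nonempty:
        corpus = Corpus(
            [docs[j] for j in nonempty], doc_ids=[doc_ids[j] for j in nonempty]
        )
        if config.k_grid:
            table = select_k(
                corpus, config.k_grid, alpha=config.alpha, beta=config.beta,
                n_sweeps=config.n_sweeps, seed=config.seed,
            )
            table.to_csv(outdir / "k_selection.csv", float_format="%.6f")
        model = fit_lda(
            corpus, config.k, alpha=config.alpha, beta=config.beta,
            n_sweeps=config.n_sweeps, seed=config.seed,
        )
        assignments = assign_topics(model, config.cutoff, label_map=label_map)
        for a in assignments:
            if a.primary is None:
                primary_topic[a.tweet_id] = None
            else:
                primary_topic[a.tweet_id] = a.label or f"topic{a.primary}"
        _write_top_words(model, outdir / "topic_top_words.csv", label_map)
        _write_assignments(assignments, outdir / "assignments.csv")
    else:
        logger.warning("no relevant tweets with LDA tokens; skipping topics")

    sent_label: dict[str, str] = {}
    for i, lab in zip(range(len(normalized)), labels):
        if lab == LAYPERSON:
            sent_label[normalized[i].id] = classify_sentiment(
                normalized[i], lexicon
            )

    rows = []
    for nt, tw_rec, lab in zip(
        normalized, matched, labels
    ):
        rows.append({
            "timestamp": tw_rec.created_at,
            "label": lab,
            "topic": primary_topic.get(nt.id) if lab != IRRELEVANT else None,
            "sentiment": sent_label.get(nt.id),
        })
    months = config.months or None
    panel = build_panel(rows, months=months)
    panel.to_csv(outdir / "panel.csv", index=False)

    if not panel.empty:
        ranking = topic_volume_ranking(panel)
        pd.DataFrame(ranking, columns=["topic", "count"]).to_csv(
            outdir / "topic_ranking.csv", index=False
        )
        lay_labels = [r["sentiment"] for r in rows if r["label"] == LAYPERSON]
        lay_topics = [r["topic"] for r in rows if r["label"] == LAYPERSON]
        if lay_labels:
            dist = sentiment_distribution(lay_labels, lay_topics)
            dist.to_csv(outdir / "sentiment_distribution.csv")
        n_months = panel["month"].nunique()
        if n_months >= 3:
            corr = correlation_table(panel)
            pd.DataFrame(
                [
                    {
                        "topic": c.topic,
                        "r": "NA" if c.r is None else f"{c.r:.3f}",
                        "p": format_p(c.p),
                        "n": c.n,
                    }
                    for c in corr
                ]
            ).to_csv(outdir / "correlation_table.csv", index=False)
            topics_present = sorted(
                t for t in panel["topic"].unique() if t != "none"
            )
            traj = pd.DataFrame(
                {t: sentiment_trajectory(panel, t) for t in topics_present}
            )
            traj.to_csv(outdir / "sentiment_trajectory.csv", float_format="%.4f")
    else:
        logger.warning("panel is empty; downstream reports skipped")

    manifest = RunManifest(
        config=_config_snapshot(config),
        n_collected=n_collected,
        n_keyword_matched=len(matched),
        n_relevant=n_relevant,
        n_promotional=n_promo,
        n_layperson=n_lay,
        version=__version__,
        seed=config.seed,
    )
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(asdict(manifest), fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info(
        "funnel: collected=%d matched=%d relevant=%d (%s promotional)",
        n_collected, len(matched), n_relevant,
        proportion_report(n_promo, n_relevant) if n_relevant else "n/a",
    )
    return manifest


def _config_snapshot(config: PipelineConfig) -> dict:
    snap = asdict(config)
    for key, val in snap.items():
        if isinstance(val, tuple):
            snap[key] = list(val)
    return snap


def _write_top_words(model, path, label_map, n: int = 20) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("topic,label,word,probability\n")
        for k in range(model.K):
            label = (label_map or {}).get(k, f"topic{k}")
            for word, prob in top_words(model, k, n=min(n, len(model.vocab))):
                fh.write(f"{k},{label},{word},{prob:.6f}\n")


def _write_assignments(assignments, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id,primary,label,selected\n")
        for a in assignments:
            sel = ";".join(f"{k}:{p:.4f}" for k, p in a.selected)
            primary = "" if a.primary is None else str(a.primary)
            fh.write(f"{a.tweet_id},{primary},{a.label or ''},{sel}\n")
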