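"""End-to-end orchestration: generate/read -> filter -> debias -> score ->
tag emotions -> summarize, with per-stage count logging and seeded
reproducibility. Re-running with an identical config reproduces
byte-identical outputs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd

from . import synth
from .circumplex import CircumplexMap, EmotionTag, arousal_score, tag_emotion
from .config import PipelineConfig
from .corpus import Corpus, Provenance, keyword_filter, read_corpus, write_corpus
from .debias import debias_corpus
from .preprocess import TokenizedTweet, preprocess_tweet
from .report import CorpusSummary, compare, summarize
from .valence import SentimentScore, ValenceLexicon, score_tweet


def preprocess_corpus(corpus: Corpus) -> dict[str, TokenizedTweet]:
    return {t.tweet_id: preprocess_tweet(t.tweet_id, t.text) for t in corpus.tweets}


def score_corpus(
    corpus: Corpus,
    tokenized: dict[str, TokenizedTweet],
    lexicon: Optional[ValenceLexicon] = None,
    alpha: float = 15.0,
    neutral_band: float = 0.05,
) -> dict[str, SentimentScore]:
    lexicon = lexicon or ValenceLexicon.default()
    return {
        t.tweet_id: score_tweet(
            tokenized[t.tweet_id], lexicon, alpha, neutral_band
        )
        for t in corpus.tweets
    }


def tag_corpus(
    corpus: Corpus,
    tokenized: dict[str, TokenizedTweet],
    scores: dict[str, SentimentScore],
    cmap: Optional[CircumplexMap] = None,
) -> list[EmotionTag]:
    cmap = cmap or CircumplexMap.default()
    tags = []
    for t in corpus.tweets:
        s = scores[t.tweet_id]
        a = arousal_score(tokenized[t.tweet_id])
        tags.append(tag_emotion(t.tweet_id, s.compound, a, cmap, s.label))
    return tags


def corpus_summary(
    name: str, corpus: Corpus, scores: dict[str, SentimentScore],
    tags: list[EmotionTag],
) -> CorpusSummary:
    labels = {t.tweet_id: scores[t.tweet_id].label for t in corpus.tweets}
    ids = {t.tweet_id for t in corpus.tweets}
    return summarize(name, labels, [g for g in tags if g.tweet_id in ids])


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage, writing all intermediates plus a provenance log to
    ``out_dir``; returns the provenance dict (stage counts and artifacts)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    def log(stage: str, n_in: int, n_out: int, **extra):
        stages.append({"stage": stage, "n_in": n_in, "n_out": n_out, **extra})

    # stage 1: obtain the raw corpus
    if config.input_path:
        corpus = read_corpus(config.input_path)
    else:
        corpus = synth.generate(config.generator_config())
        write_corpus(corpus, out / "raw.jsonl")
        corpus.truth.to_csv(out / "truth.csv", index=False)
    n_raw = len(corpus)
    log("collect", n_raw, n_raw)

    # stage 2: topic filter (and optional retweet drop)
    corpus = keyword_filter(corpus, config.root_terms)
    if config.drop_retweets:
        corpus = corpus.subset(
            [t.tweet_id for t in corpus.tweets if not t.is_retweet],
            corpus.provenance,
        )
    log("keyword_filter", n_raw, len(corpus))

    # stage 3: preprocess + valence scores (debias consumes both)
    tokenized = preprocess_corpus(corpus)
    lexicon = ValenceLexicon.default()
    scores = score_corpus(corpus, tokenized, lexicon, config.alpha,
                          config.neutral_band)
    log("preprocess", len(corpus), len(tokenized))

    # stage 4: debias
    compounds = {tid: s.compound for tid, s in scores.items()}
    clean, bots, marketing, dreport, _ = debias_corpus(
        corpus,
        tokenized,
        compounds,
        weights=config.bot_feature_weights,
        threshold=config.bot_threshold,
        human_mobile_fraction=config.human_mobile_fraction,
        band_halfwidth=config.follower_band_halfwidth,
        human_profile=config.human_pos_profile,
        human_std=config.human_compound_std,
    )
    write_corpus(clean, out / "clean.jsonl")
    write_corpus(bots, out / "bots.jsonl")
    write_corpus(marketing, out / "marketing.jsonl")
    (out / "debias_report.json").write_text(
        json.dumps(dreport.as_dict(), indent=2, sort_keys=True)
    )
    log("debias", len(corpus), len(clean), report=dreport.as_dict())

    # stage 5: emotions for the debiased and the biased comparison corpus
    # (biased = humans + bots, marketing excluded)
    biased = corpus.subset(
        [t.tweet_id for t in clean.tweets] + [t.tweet_id for t in bots.tweets],
        Provenance.RAW,
    )
    tags_all = tag_corpus(corpus, tokenized, scores)
    pd.DataFrame(
        [
            {
                "tweet_id": g.tweet_id,
                "compound": round(scores[g.tweet_id].compound, 6),
                "label": scores[g.tweet_id].label,
                "arousal": round(g.arousal, 6),
                "emotion": g.emotion,
                "quadrant": g.quadrant,
                "primary": g.primary,
            }
            for g in tags_all
        ]
    ).to_csv(out / "emotions.csv", index=False)
    log("emotions", len(corpus), len(tags_all))

    # stage 6: summaries + comparison
    summary_clean = corpus_summary("debiased", clean, scores, tags_all)
    summary_biased = corpus_summary("biased", biased, scores, tags_all)
    table = compare(summary_clean, summary_biased)
    (out / "summary_debiased.json").write_text(
        json.dumps(summary_clean.as_dict(), indent=2, sort_keys=True)
    )
    (out / "summary_biased.json").write_text(
        json.dumps(summary_biased.as_dict(), indent=2, sort_keys=True)
    )
    table.to_frame().to_csv(out / "comparison.csv", index=False)
    log("report", len(clean) + len(biased), 2)

    provenance = {
        "config": config.resolved(),
        "stages": stages,
        "artifacts": sorted(p.name for p in out.iterdir()),
    }
    (out / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True)
    )
    return provenance
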