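"""Social-bot detection features, account scoring, and corpus debiasing.

Six account-level behavioral features, each normalized to [0, 1] where 1
is maximally bot-like, are combined as a weighted mean into a single bot
score; accounts at or above the threshold (default 0.5) are flagged and all
their tweets removed. Marketing posts are then removed by keyword (e.g.
"1100mah", a battery-strength term endemic to hookah-pen promotions), so
the three output corpora — clean, bots-only, marketing-only — partition the
input exactly.

Features:

* timing regularity — 1/(1+CV) of inter-tweet intervals; periodic posting
  schedules give CV near 0, human bursty behavior gives CV well above 1;
* spam — fraction of the account's tweets containing a known spam phrase;
* client ratio — deviation of the account's mobile:desktop mix from the
  average human mobile fraction;
* follower ratio — extremeness of log10(followers/followees) relative to a
  human band;
* content — total-variation distance of the account's noun/verb/adverb
  profile from a human reference profile;
* sentiment dispersion — accounts that repeat near-identical sentiment
  scores (template posting) score high.

A feature that cannot be computed (too few tweets, no tagged tokens, ...)
is reported missing and excluded with weight renormalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from . import resources
from .corpus import Corpus, Provenance, Tweet
from .preprocess import TokenizedTweet, preprocess_tweet

FEATURE_NAMES = (
    "timing_regularity",
    "spam_score",
    "client_ratio_deviation",
    "follower_ratio_score",
    "content_score",
    "sentiment_feature_score",
)

#: Human-baseline configuration. These are declared pipeline defaults (the
#: source study does not report its calibration): average human mobile
#: share, the half-width (in log10 units) of the "ordinary" follower ratio
#: band, a pooled noun/verb/adverb profile, and the typical spread of human
#: per-tweet compound scores.
DEFAULT_HUMAN_MOBILE_FRACTION = 0.7
DEFAULT_FOLLOWER_BAND_HALFWIDTH = 2.0
DEFAULT_HUMAN_POS_PROFILE = (0.45, 0.35, 0.20)  # noun, verb, adverb
DEFAULT_HUMAN_COMPOUND_STD = 0.6
DEFAULT_BOT_THRESHOLD = 0.5


@dataclass
class BotFeatures:
    """Feature values in [0, 1]; None marks a missing feature."""

    timing_regularity: Optional[float] = None
    spam_score: Optional[float] = None
    client_ratio_deviation: Optional[float] = None
    follower_ratio_score: Optional[float] = None
    content_score: Optional[float] = None
    sentiment_feature_score: Optional[float] = None

    def as_dict(self) -> dict[str, Optional[float]]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


@dataclass
class BotScore:
    account_id: str
    features: BotFeatures
    combined: Optional[float]  # None when every feature is missing
    is_bot: bool
    undecidable: bool = False


def timing_regularity(timestamps: Sequence[float]) -> Optional[float]:
    """1/(1+CV) of inter-tweet intervals; 1.0 for a perfectly periodic
    account. Missing (None) with fewer than 2 distinct timestamps."""
    ts = sorted(set(timestamps))
    if len(ts) < 2:
        return None
    intervals = np.diff(ts)
    mean = float(np.mean(intervals))
    if mean == 0.0:
        return None
    cv = float(np.std(intervals)) / mean
    return 1.0 / (1.0 + cv)


def spam_score(
    tokenized: Sequence[TokenizedTweet],
    spam_phrases: Optional[Iterable[str]] = None,
) -> float:
    """Fraction of the account's tweets containing any known spam phrase.

    Phrases are passed through the same tokenize/normalize pipeline as the
    tweets, so the match is on normalized token n-grams (stop words inside
    a phrase, as in "click here", drop out on both sides)."""
    if spam_phrases is None:
        spam_phrases = resources.load_spam_phrases()
    phrases = list(spam_phrases)
    if not phrases:
        raise ValueError("spam phrase list must be non-empty")
    phrase_tokens = [
        tuple(preprocess_tweet("", p).unstemmed) for p in phrases
    ]
    phrase_tokens = [p for p in phrase_tokens if p]
    hits = 0
    for tt in tokenized:
        toks = tt.unstemmed
        found = False
        for ph in phrase_tokens:
            m = len(ph)
            for i in range(len(toks) - m + 1):
                if tuple(toks[i : i + m]) == ph:
                    found = True
                    break
            if found:
                break
        hits += found
    return hits / len(tokenized) if tokenized else 0.0


def client_ratio_deviation(
    tweets: Sequence[Tweet],
    human_mobile_fraction: float = DEFAULT_HUMAN_MOBILE_FRACTION,
) -> Optional[float]:
    """|observed mobile share − human share| scaled to [0, 1]; tweets from
    "other" clients are excluded; missing when only "other" remains."""
    if not 0.0 < human_mobile_fraction < 1.0:
        raise ValueError("human_mobile_fraction must be in (0, 1)")
    counted = [t for t in tweets if t.source_client.value in ("mobile", "desktop")]
    if not counted:
        return None
    observed = sum(t.source_client.value == "mobile" for t in counted) / len(counted)
    scale = max(human_mobile_fraction, 1.0 - human_mobile_fraction)
    return abs(observed - human_mobile_fraction) / scale


def follower_ratio_score(
    followers: int,
    followees: int,
    band_halfwidth: float = DEFAULT_FOLLOWER_BAND_HALFWIDTH,
) -> float:
    """Extremeness of log10((followers+1)/(followees+1)) relative to the
    human band, clipped to [0, 1]."""
    ratio = math.log10((followers + 1) / (followees + 1))
    return min(1.0, abs(ratio) / band_halfwidth)


def content_score(
    pos_tag_lists: Sequence[Sequence[str]],
    human_profile: tuple[float, float, float] = DEFAULT_HUMAN_POS_PROFILE,
) -> Optional[float]:
    """Total-variation distance between the account's pooled
    noun/verb/adverb frequencies and the human reference profile."""
    counts = {"noun": 0, "verb": 0, "adverb": 0}
    for tags in pos_tag_lists:
        for tag in tags:
            if tag in counts:
                counts[tag] += 1
    total = sum(counts.values())
    if total == 0:
        return None
    obs = np.array([counts["noun"], counts["verb"], counts["adverb"]]) / total
    ref = np.asarray(human_profile, dtype=float)
    ref = ref / ref.sum()
    return float(0.5 * np.abs(obs - ref).sum())


def sentiment_feature_score(
    compounds: Sequence[float],
    human_std: float = DEFAULT_HUMAN_COMPOUND_STD,
) -> Optional[float]:
    """1 − dispersion ratio of per-tweet compound scores: an account that
    repeats near-identical sentiment scores high. Missing with fewer than 3
    scored tweets."""
    if len(compounds) < 3:
        return None
    std = float(np.std(compounds))
    return max(0.0, min(1.0, 1.0 - std / human_std))


def combine_bot_score(
    account_id: str,
    features: BotFeatures,
    weights: Optional[dict[str, float]] = None,
    threshold: float = DEFAULT_BOT_THRESHOLD,
) -> BotScore:
    """Weighted mean of available features; missing features drop out with
    weight renormalization. If every feature is missing the account is
    undecidable and conservatively retained."""
    if weights is None:
        weights = {name: 1.0 for name in FEATURE_NAMES}
    if any(w < 0 for w in weights.values()):
        raise ValueError("weights must be non-negative")
    num = den = 0.0
    for name in FEATURE_NAMES:
        value = getattr(features, name)
        w = weights.get(name, 0.0)
        if value is None or w == 0.0:
            continue
        num += w * value
        den += w
    if den == 0.0:
        return BotScore(account_id, features, None, False, undecidable=True)
    combined = num / den
    return BotScore(account_id, features, combined, combined >= threshold)


def marketing_filter(
    tweets: Sequence[Tweet],
    tokenized: dict[str, TokenizedTweet],
    marketing_keywords: Optional[Iterable[str]] = None,
) -> tuple[list[Tweet], list[Tweet]]:
    """Split tweets into (kept, removed) by marketing-keyword occurrence in
    the normalized text. An empty keyword list warns and keeps everything."""
    if marketing_keywords is None:
        marketing_keywords = resources.load_marketing_keywords()
    kws = {k.lower() for k in marketing_keywords}
    if not kws:
        import warnings

        warnings.warn("empty marketing keyword list; marketing filter is a no-op")
        return list(tweets), []
    kept, removed = [], []
    for t in tweets:
        toks = set(tokenized[t.tweet_id].unstemmed)
        (removed if toks & kws else kept).append(t)
    return kept, removed


@dataclass
class DebiasReport:
    n_input: int
    n_bot_removed: int
    n_marketing_removed: int
    n_clean: int = field(init=False)
    n_biased_comparison: int = field(init=False)  # input minus marketing
    pct_bot_removed: float = field(init=False)
    pct_marketing_removed: float = field(init=False)
    n_accounts_flagged: int = 0
    n_accounts_undecidable: int = 0

    def __post_init__(self):
        self.n_clean = self.n_input - self.n_bot_removed - self.n_marketing_removed
        self.n_biased_comparison = self.n_input - self.n_marketing_removed
        self.pct_bot_removed = round(100.0 * self.n_bot_removed / self.n_input, 2)
        self.pct_marketing_removed = round(
            100.0 * self.n_marketing_removed / self.n_input, 2
        )

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_bot_removed": self.n_bot_removed,
            "n_marketing_removed": self.n_marketing_removed,
            "n_clean": self.n_clean,
            "n_biased_comparison": self.n_biased_comparison,
            "pct_bot_removed": self.pct_bot_removed,
            "pct_marketing_removed": self.pct_marketing_removed,
            "n_accounts_flagged": self.n_accounts_flagged,
            "n_accounts_undecidable": self.n_accounts_undecidable,
        }


def score_accounts(
    corpus: Corpus,
    tokenized: dict[str, TokenizedTweet],
    compounds: Optional[dict[str, float]] = None,
    weights: Optional[dict[str, float]] = None,
    threshold: float = DEFAULT_BOT_THRESHOLD,
    human_mobile_fraction: float = DEFAULT_HUMAN_MOBILE_FRACTION,
    band_halfwidth: float = DEFAULT_FOLLOWER_BAND_HALFWIDTH,
    human_profile: tuple[float, float, float] = DEFAULT_HUMAN_POS_PROFILE,
    human_std: float = DEFAULT_HUMAN_COMPOUND_STD,
) -> dict[str, BotScore]:
    """Compute the full feature set and combined bot score per account."""
    by_account: dict[str, list[Tweet]] = {aid: [] for aid in corpus.accounts}
    for t in corpus.tweets:
        by_account[t.account_id].append(t)
    scores: dict[str, BotScore] = {}
    for aid, acc in corpus.accounts.items():
        tweets = sorted(by_account[aid], key=lambda t: t.timestamp)
        tts = [tokenized[t.tweet_id] for t in tweets]
        feats = BotFeatures(
            timing_regularity=timing_regularity([t.timestamp for t in tweets]),
            spam_score=spam_score(tts) if tts else None,
            client_ratio_deviation=client_ratio_deviation(
                tweets, human_mobile_fraction
            ),
            follower_ratio_score=follower_ratio_score(
                acc.followers, acc.followees, band_halfwidth
            ),
            content_score=content_score([tt.pos_tags for tt in tts], human_profile),
            sentiment_feature_score=(
                sentiment_feature_score(
                    [compounds[t.tweet_id] for t in tweets], human_std
                )
                if compounds is not None
                else None
            ),
        )
        scores[aid] = combine_bot_score(aid, feats, weights, threshold)
    return scores


def debias_corpus(
    corpus: Corpus,
    tokenized: dict[str, TokenizedTweet],
    compounds: Optional[dict[str, float]] = None,
    weights: Optional[dict[str, float]] = None,
    threshold: float = DEFAULT_BOT_THRESHOLD,
    marketing_keywords: Optional[Iterable[str]] = None,
    **baseline_kwargs,
) -> tuple[Corpus, Corpus, Corpus, DebiasReport, dict[str, BotScore]]:
    """Remove bot-account tweets, then marketing-keyword tweets.

    Returns (clean, bots_only, marketing_only, report, account_scores); the
    three corpora partition the input exactly, and a bot tweet containing a
    marketing keyword counts as bot (bot removal is applied first)."""
    scores = score_accounts(
        corpus, tokenized, compounds, weights, threshold, **baseline_kwargs
    )
    bot_accounts = {aid for aid, s in scores.items() if s.is_bot}
    bot_tweets = [t for t in corpus.tweets if t.account_id in bot_accounts]
    surviving = [t for t in corpus.tweets if t.account_id not in bot_accounts]
    kept, mkt_tweets = marketing_filter(surviving, tokenized, marketing_keywords)
    clean = corpus.subset([t.tweet_id for t in kept], Provenance.DEBIASED)
    bots = corpus.subset([t.tweet_id for t in bot_tweets], Provenance.BOTS_ONLY)
    marketing = corpus.subset(
        [t.tweet_id for t in mkt_tweets], Provenance.MARKETING_ONLY
    )
    report = DebiasReport(len(corpus), len(bots), len(marketing))
    report.n_accounts_flagged = len(bot_accounts)
    report.n_accounts_undecidable = sum(s.undecidable for s in scores.values())
    return clean, bots, marketing, report, scores
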