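"""Seeded synthetic tweet corpus with planted human / bot / marketing
structure and exact ground-truth sentiment.

The study population this emulates: legitimate human accounts posting
sentiment-bearing hookah talk with bursty (heavy-tailed) timing and mostly
mobile clients; social-bot accounts posting near-periodic spam from a
single client with extreme follower:followee ratios and repetitive
sentiment; and marketing accounts embedding product keywords (e.g.
"1100mah") in otherwise positive promotional text.

Text is assembled from slot-filling templates over the package's own
valence lexicon, so every tweet's planted sentiment label is exact by
construction. Controlled rates of emphatic features (ALL-CAPS, "!",
character elongation, emoticons, "but" clauses, negation) exercise the
grammar rules of the scorer; tweets carrying negation or a contrast clause
are flagged in the ground-truth sidecar so unambiguous subsets can be
selected.

The same seed always yields a byte-identical corpus file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .corpus import (
    WINDOW_END,
    WINDOW_START,
    Account,
    ClientSource,
    Corpus,
    Provenance,
    Tweet,
)
from . import resources

ROOTS = ("hookah", "shisha", "sheesha", "hooka", "sesh")

# sentiment word pools, split by arousal register so positive tweets fall in
# both upper (active) and lower (calm) circumplex quadrants
POS_HIGH = (
    "wonderful", "amazing", "great", "happy", "awesome", "excellent",
    "fantastic", "delicious", "perfect", "beautiful", "excited", "fun",
)
POS_LOW = ("calm", "relaxed", "relaxing", "serene", "peaceful", "mellow",
           "cozy", "chill")
NEG_HIGH = ("horrible", "terrible", "awful", "nasty", "disgusting", "gross",
            "angry", "mad", "stressed", "upset", "nervous")
NEG_LOW = ("sad", "unhappy", "depressed", "bored", "miserable", "lonely")

# strong/weak pools for "but"-contrast templates: the trailing (1.5x) clause
# must dominate the 0.5x opener so the planted label survives scoring
STRONG_POS = ("wonderful", "amazing", "great", "awesome", "perfect")
STRONG_NEG = ("horrible", "terrible", "disgusting", "miserable", "nasty")
WEAK_POS = ("nice", "smooth", "fresh", "sweet")
WEAK_NEG = ("boring", "stale", "harsh", "bitter")

POS_TEMPLATES = (
    "so {w} smoking {root} with friends tonight",
    "this {root} is {w}",
    "had a {w} time at the {root} lounge",
    "feeling {w} after that {root} session",
    "{w} {root} flavors at this spot",
)
NEG_TEMPLATES = (
    "this {root} tastes {w}",
    "the {root} here was {w}",
    "feeling {w} after {root} tonight",
    "{root} smoke makes me {w}",
    "that {w} {root} ruined the night",
)
NEU_TEMPLATES = (
    "smoking {root} at the lounge tonight",
    "anyone know a {root} spot open late",
    "picked up coals for the {root}",
    "watching the game with a {root}",
    "{root} and mint tea again",
)
BOT_TEMPLATES = (
    "{w} {root} deals {spam}",
    "{spam} for {w} {root} prices",
    "{root} fans {spam} before its gone",
)
MARKETING_TEMPLATES = (
    "new {root} pen {kw} with {w} flavors buy now",
    "restocked the {w} {root} line use code {kw}",
    "{kw} sale on {w} {root} gear today",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition defaults: 120/60/20 human/bot/marketing accounts at
    equal mean posting rates, so 30% of tweets come from bots and ~10% from
    marketing accounts; the human sentiment mix (59.5/30/10.5) mirrors the
    debiased label shares this kind of corpus exhibits."""

    n_human_accounts: int = 120
    n_bot_accounts: int = 60
    n_marketing_accounts: int = 20
    tweets_per_account_mean: float = 20.0
    sentiment_mix: tuple[float, float, float] = (0.595, 0.30, 0.105)
    bot_sentiment_mix: tuple[float, float, float] = (0.10, 0.75, 0.15)
    bot_period_seconds: float = 3600.0
    bot_timing_jitter: float = 0.05
    human_interarrival_shape: float = 1.2  # lognormal sigma
    human_interarrival_median: float = 21600.0  # seconds
    human_mobile_fraction: float = 0.7
    p_booster: float = 0.15
    p_caps: float = 0.05
    p_exclaim: float = 0.12
    p_elongation: float = 0.05
    p_emoticon: float = 0.10
    p_negation: float = 0.05
    p_contrast: float = 0.05
    p_bot_spam: float = 0.8
    p_pos_high_arousal: float = 0.62
    p_neg_high_arousal: float = 0.46
    marketing_keywords: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        for mix in (self.sentiment_mix, self.bot_sentiment_mix):
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"sentiment mix {mix} must sum to 1")
            if any(p < 0 for p in mix):
                raise ValueError("mix probabilities must be non-negative")
        if min(self.n_human_accounts, self.n_bot_accounts,
               self.n_marketing_accounts) < 0:
            raise ValueError("account counts must be non-negative")
        if (self.n_human_accounts + self.n_bot_accounts
                + self.n_marketing_accounts) == 0:
            raise ValueError("at least one account is required")
        if not 0 <= self.bot_timing_jitter < 1:
            raise ValueError("bot_timing_jitter must be in [0, 1)")
        if self.tweets_per_account_mean <= 0 or self.human_interarrival_shape <= 0:
            raise ValueError("rates and shapes must be positive")


def _decorate(
    word: str, rng: np.random.Generator, cfg: GeneratorConfig, polarity: str
) -> tuple[str, str, str]:
    """Apply emphatic decorations; returns (word, prefix, suffix)."""
    prefix = suffix = ""
    if rng.random() < cfg.p_booster:
        prefix = rng.choice(["very", "really", "so", "extremely"]) + " "
    if rng.random() < cfg.p_elongation:
        word = word + word[-1] * 3
    if rng.random() < cfg.p_caps:
        word = word.upper()
    if rng.random() < cfg.p_exclaim:
        suffix += "!"
    if polarity != "neutral" and rng.random() < cfg.p_emoticon:
        suffix += " :)" if polarity == "positive" else " :("
    return word, prefix, suffix


def _human_text(
    rng: np.random.Generator, cfg: GeneratorConfig
) -> tuple[str, str, bool, bool]:
    """One human tweet; returns (text, label, has_negation, has_contrast)."""
    label = ["positive", "negative", "neutral"][
        rng.choice(3, p=list(cfg.sentiment_mix))
    ]
    root = rng.choice(ROOTS)
    if label == "neutral":
        text = rng.choice(NEU_TEMPLATES).format(root=root)
        if rng.random() < cfg.p_exclaim:
            text += "!"
        return text, label, False, False
    if rng.random() < cfg.p_contrast:
        if label == "positive":
            opener, target = rng.choice(WEAK_NEG), rng.choice(STRONG_POS)
        else:
            opener, target = rng.choice(WEAK_POS), rng.choice(STRONG_NEG)
        text = f"the place was {opener} but the {root} was {target}"
        return text, label, False, True
    if rng.random() < cfg.p_negation:
        if label == "positive":
            text = f"this {root} isnt {rng.choice(STRONG_NEG)} at all"
        else:
            text = f"the {root} here isnt {rng.choice(STRONG_POS)} at all"
        return text, label, True, False
    if label == "positive":
        pool = POS_HIGH if rng.random() < cfg.p_pos_high_arousal else POS_LOW
        template = rng.choice(POS_TEMPLATES)
    else:
        pool = NEG_HIGH if rng.random() < cfg.p_neg_high_arousal else NEG_LOW
        template = rng.choice(NEG_TEMPLATES)
    word, prefix, suffix = _decorate(str(rng.choice(pool)), rng, cfg, label)
    text = template.format(root=root, w=prefix + word) + suffix
    return text, label, False, False


def _timestamps_human(
    rng: np.random.Generator, cfg: GeneratorConfig, n: int
) -> list[int]:
    mu = np.log(cfg.human_interarrival_median)
    gaps = rng.lognormal(mu, cfg.human_interarrival_shape, size=max(n - 1, 0))
    span = float(gaps.sum())
    window = WINDOW_END - WINDOW_START
    if span >= window:
        gaps = gaps * (0.5 * window / span)
        span = float(gaps.sum())
    t0 = rng.uniform(WINDOW_START, WINDOW_END - span)
    return [int(t) for t in np.concatenate([[t0], t0 + np.cumsum(gaps)])]


def _timestamps_bot(
    rng: np.random.Generator, cfg: GeneratorConfig, n: int
) -> list[int]:
    j = cfg.bot_timing_jitter
    gaps = cfg.bot_period_seconds * (1.0 + rng.uniform(-j, j, size=max(n - 1, 0)))
    span = float(gaps.sum())
    t0 = rng.uniform(WINDOW_START, WINDOW_END - span)
    return [int(t) for t in np.concatenate([[t0], t0 + np.cumsum(gaps)])]


def generate(config: Optional[GeneratorConfig] = None) -> Corpus:
    """Build a corpus with ground-truth roles on every account and a
    per-tweet truth sidecar (``corpus.truth``)."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    keywords = cfg.marketing_keywords or resources.load_marketing_keywords()
    spam_phrases = resources.load_spam_phrases()

    tweets: list[Tweet] = []
    accounts: dict[str, Account] = {}
    truth_rows: list[dict] = []
    counter = 0

    roles = (
        [("human", f"h{i:04d}") for i in range(cfg.n_human_accounts)]
        + [("bot", f"b{i:04d}") for i in range(cfg.n_bot_accounts)]
        + [("marketing", f"m{i:04d}") for i in range(cfg.n_marketing_accounts)]
    )
    for role, aid in roles:
        n = max(1, int(rng.poisson(cfg.tweets_per_account_mean)))
        if role == "bot":
            ts = _timestamps_bot(rng, cfg, n)
            followers = int(rng.integers(0, 50))
            followees = int(rng.integers(2000, 10001))
            client = (ClientSource.DESKTOP if rng.random() < 0.8
                      else ClientSource.MOBILE)
            # bots are template repeaters: one phrase, one word, one frame
            bot_label = ["positive", "negative", "neutral"][
                rng.choice(3, p=list(cfg.bot_sentiment_mix))
            ]
            bot_word = str(rng.choice(
                POS_HIGH if bot_label == "positive"
                else NEG_HIGH if bot_label == "negative" else ("fresh",)
            )) if bot_label != "neutral" else "daily"
            bot_phrase = str(rng.choice(spam_phrases))
            bot_template = str(rng.choice(BOT_TEMPLATES))
        else:
            ts = _timestamps_human(rng, cfg, n)
            followers = int(10 ** rng.uniform(1.5, 3.0))
            followees = max(1, int(followers * 10 ** rng.normal(0.0, 0.3)))
            client = None

        acc_tweet_ids = []
        for i in range(n):
            tid = f"t{counter:07d}"
            counter += 1
            has_neg = has_con = False
            if role == "human":
                text, label, has_neg, has_con = _human_text(rng, cfg)
                p_mob = cfg.human_mobile_fraction
                p_other = min(0.05, 1.0 - p_mob)
                src = ClientSource(
                    ["mobile", "desktop", "other"][
                        rng.choice(3, p=[p_mob, 1.0 - p_mob - p_other, p_other])
                    ]
                )
                mention = int(rng.poisson(0.5))
                retweet = bool(rng.random() < 0.15)
            elif role == "bot":
                label = bot_label
                root = str(rng.choice(ROOTS))
                if rng.random() < cfg.p_bot_spam:
                    text = bot_template.format(
                        root=root, w=bot_word, spam=bot_phrase
                    )
                else:
                    text = f"{bot_word} {root} deals every day"
                src = client
                mention = int(rng.poisson(2.0))
                retweet = bool(rng.random() < 0.3)
            else:  # marketing
                label = "positive"
                root = str(rng.choice(ROOTS))
                text = str(rng.choice(MARKETING_TEMPLATES)).format(
                    root=root,
                    kw=str(rng.choice(list(keywords))),
                    w=str(rng.choice(POS_HIGH)),
                )
                src = ClientSource.MOBILE if rng.random() < 0.5 else ClientSource.DESKTOP
                mention = int(rng.poisson(1.0))
                retweet = bool(rng.random() < 0.1)
            tweets.append(
                Tweet(tid, aid, float(ts[i]), text, src, retweet, mention)
            )
            acc_tweet_ids.append(tid)
            truth_rows.append(
                {
                    "tweet_id": tid,
                    "account_id": aid,
                    "role": role,
                    "planted_sentiment": label,
                    "has_negation": has_neg,
                    "has_contrast": has_con,
                }
            )
        accounts[aid] = Account(aid, followers, followees, acc_tweet_ids, role)

    truth = pd.DataFrame(truth_rows)
    corpus = Corpus(tweets, accounts, Provenance.RAW, truth)
    corpus.validate()
    return corpus


def ground_truth(corpus: Corpus) -> pd.DataFrame:
    """The per-tweet (role, planted sentiment) table recorded at generation
    time; raises if the corpus was not generated by this module."""
    if corpus.truth is None:
        raise ValueError("corpus has no ground-truth sidecar table")
    return corpus.truth.copy()
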