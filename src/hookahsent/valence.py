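"""Rule-based sentiment scoring with a valence lexicon and grammar heuristics.

Each lexicon word carries a valence on a [-4, 4] spectrum (e.g. "horrible"
-2.5, "wonderful" 2.7). A tweet's raw score is the sum of token valences
after four grammar rules:

* **degree modifiers** — a booster ("very", "extremely") immediately before
  a valence word makes it count twice;
* **emphasis** — an ALL-CAPS valence word, or a valence word in a clause
  ended by "!", also counts twice; doublings do not stack past a total
  multiplier of 4;
* **negation** — a negator within the three scoring tokens before a valence
  word flips its sign;
* **contrast** — "but" splits the tweet: words before it are down-weighted
  (x0.5) and words after it up-weighted (x1.5), realizing the polarity
  shift toward the trailing clause.

The raw sum is squashed to a compound score in (-1, 1) by
``x / sqrt(x^2 + alpha)`` with alpha = 15, and labeled positive / negative /
neutral against a symmetric +-0.05 band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

from . import resources
from .preprocess import TokenizedTweet
from .stemmer import stem

DEFAULT_ALPHA = 15.0
DEFAULT_NEUTRAL_BAND = 0.05
NEGATION_WINDOW = 3
CONTRAST_BEFORE = 0.5
CONTRAST_AFTER = 1.5
MULTIPLIER_CAP = 4.0


@dataclass(frozen=True)
class ValenceLexicon:
    valences: dict[str, float]
    boosters: frozenset[str]
    negators: frozenset[str]
    contrast_words: frozenset[str]
    stemmed_valences: dict[str, float]

    def __post_init__(self):
        bad = [w for w, v in self.valences.items() if not -4.0 <= v <= 4.0]
        if bad:
            raise ValueError(f"valences outside [-4, 4]: {bad[:5]}")
        overlap = set(self.valences) & (
            self.boosters | self.negators | self.contrast_words
        )
        if overlap:
            raise ValueError(f"function-word lists overlap lexicon: {overlap}")

    @classmethod
    def build(
        cls,
        valences: dict[str, float],
        boosters: Iterable[str],
        negators: Iterable[str],
        contrast_words: Iterable[str],
    ) -> "ValenceLexicon":
        stemmed: dict[str, float] = {}
        for w in sorted(valences):  # sorted => deterministic first-wins
            s = stem(w.lower())
            stemmed.setdefault(s, valences[w])
        return cls(
            dict(valences),
            frozenset(boosters),
            frozenset(negators),
            frozenset(contrast_words),
            stemmed,
        )

    @classmethod
    def default(cls) -> "ValenceLexicon":
        return cls.build(
            resources.load_valence_table(),
            resources.load_wordset("boosters"),
            resources.load_wordset("negators"),
            resources.load_wordset("contrast"),
        )


@dataclass(frozen=True)
class SentimentScore:
    tweet_id: str
    raw_sum: float
    compound: float
    label: str  # positive | negative | neutral


def token_valence(token: str, lexicon: ValenceLexicon) -> Optional[float]:
    """Exact lookup, then stemmed-key fallback; None if out of lexicon."""
    if token in lexicon.valences:
        return lexicon.valences[token]
    return lexicon.stemmed_valences.get(stem(token))


def classify(compound: float, neutral_band: float = DEFAULT_NEUTRAL_BAND) -> str:
    if neutral_band < 0:
        raise ValueError("neutral_band must be >= 0")
    if compound >= neutral_band:
        return "positive"
    if compound <= -neutral_band:
        return "negative"
    return "neutral"


def score_tweet(
    tt: TokenizedTweet,
    lexicon: Optional[ValenceLexicon] = None,
    alpha: float = DEFAULT_ALPHA,
    neutral_band: float = DEFAULT_NEUTRAL_BAND,
) -> SentimentScore:
    """Apply the lexicon and grammar rules to one preprocessed tweet."""
    if lexicon is None:
        lexicon = ValenceLexicon.default()
    toks = tt.unstemmed
    n = len(toks)
    contrast_idx = next(
        (i for i, w in enumerate(toks) if w in lexicon.contrast_words), None
    )
    raw = 0.0
    for i, w in enumerate(toks):
        if w in lexicon.boosters or w in lexicon.negators or w in lexicon.contrast_words:
            continue
        v = token_valence(w, lexicon)
        if v is None:
            continue
        mult = 1.0
        if i > 0 and toks[i - 1] in lexicon.boosters:
            mult *= 2.0
        if tt.allcaps[i]:
            mult *= 2.0
        if tt.exclaimed[i]:
            mult *= 2.0
        mult = min(mult, MULTIPLIER_CAP)
        if any(
            toks[j] in lexicon.negators
            for j in range(max(0, i - NEGATION_WINDOW), i)
        ):
            v = -v
        weight = 1.0
        if contrast_idx is not None:
            weight = CONTRAST_AFTER if i > contrast_idx else CONTRAST_BEFORE
        raw += v * mult * weight
    compound = raw / math.sqrt(raw * raw + alpha) if raw != 0.0 else 0.0
    return SentimentScore(tt.tweet_id, raw, compound, classify(compound, neutral_band))


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    undefined: bool  # a zero-denominator ratio was reported as 0


def evaluate(
    predicted: list[str], gold: list[str]
) -> tuple[dict[str, ClassMetrics], float]:
    """Per-class precision/recall/F (F = 2PR/(P+R)) and the macro-F.

    Zero-denominator ratios are reported as 0 with the ``undefined`` flag
    set. Macro-F is the unweighted mean over the classes present in either
    list.
    """
    if len(predicted) != len(gold):
        raise ValueError("predicted and gold label lists differ in length")
    classes = sorted(set(predicted) | set(gold))
    out: dict[str, ClassMetrics] = {}
    for c in classes:
        tp = sum(1 for p, g in zip(predicted, gold) if p == c and g == c)
        fp = sum(1 for p, g in zip(predicted, gold) if p == c and g != c)
        fn = sum(1 for p, g in zip(predicted, gold) if p != c and g == c)
        undef = False
        if tp + fp == 0:
            prec, undef = 0.0, True
        else:
            prec = tp / (tp + fp)
        if tp + fn == 0:
            rec, undef = 0.0, True
        else:
            rec = tp / (tp + fn)
        if prec + rec == 0:
            f1, undef = 0.0, True
        else:
            f1 = 2 * prec * rec / (prec + rec)
        out[c] = ClassMetrics(prec, rec, f1, undef)
    macro = sum(m.f1 for m in out.values()) / len(out) if out else 0.0
    return out, macro
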