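"""Valence-arousal circumplex emotion tagging and the n-gram classifier.

Twenty named emotions sit on the unit circle of the valence (pleasant -
unpleasant) x arousal (activation - deactivation) plane, grouped into four
quadrants: highly positive (active, alert, excited, elated, happy,
pleasant), passive positive (contented, serene, calm, relaxed, subdued),
subdued negative (sad, unhappy, depressed, bored), and highly negative
(tense, nervous, stressed, upset, unpleasant). A scored tweet is placed at
(compound valence, arousal) and tagged with the nearest anchor; the 20
emotions reduce to 5 primaries (anger, fear, joy, sadness, disgust) by a
configurable table.

Arousal is not directly observable from a valence lexicon, so it is
operationalized here as the mean of an arousal word lexicon plus an
emphasis-intensity term (exclamations, ALL-CAPS, elongations), squashed
into [-1, 1].

The supervised counterpart to the rule engine is a linear max-margin
classifier over uni+bigram counts (scikit-learn CountVectorizer +
LinearSVC), with stratified k-fold cross-validation reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.svm import LinearSVC

from . import resources
from .preprocess import TokenizedTweet

PRIMARIES = ("anger", "fear", "joy", "sadness", "disgust")
QUADRANTS = ("highly_positive", "passive_positive", "subdued_negative",
             "highly_negative")


@dataclass(frozen=True)
class CircumplexMap:
    anchors: dict[str, tuple[float, float]]   # emotion -> (valence, arousal)
    quadrant_of: dict[str, str]
    primary_of: dict[str, str]

    def __post_init__(self):
        if len(self.anchors) != 20:
            raise ValueError(f"expected 20 anchors, got {len(self.anchors)}")
        sizes = {q: 0 for q in QUADRANTS}
        for e in self.anchors:
            sizes[self.quadrant_of[e]] += 1
        if (sizes["highly_positive"], sizes["passive_positive"],
                sizes["subdued_negative"], sizes["highly_negative"]) != (6, 5, 4, 5):
            raise ValueError(f"quadrant sizes {sizes} do not partition 6+5+4+5")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CircumplexMap":
        anchors, quad, prim = {}, {}, {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, v, a, q, p = line.split("\t")
            anchors[name] = (float(v), float(a))
            quad[name], prim[name] = q, p
        return cls(anchors, quad, prim)

    @classmethod
    def default(cls) -> "CircumplexMap":
        return cls.from_tsv(resources.DATA_DIR / "circumplex.tsv")


@dataclass(frozen=True)
class EmotionTag:
    tweet_id: str
    valence: float
    arousal: float
    emotion: str
    quadrant: str  # one of QUADRANTS or "neutral"
    primary: str   # one of PRIMARIES or "none"


def arousal_score(
    tt: TokenizedTweet,
    arousal_lexicon: Optional[dict[str, float]] = None,
    emphasis_gain: float = 0.8,
) -> float:
    """Arousal in [-1, 1] from arousal-lexicon words plus surface emphasis.

    With no signal at all the score is 0. Emphasis (exclamations, ALL-CAPS,
    elongations) contributes a saturating activation term, so an emphatic
    tweet scores high-arousal even without arousal words.
    """
    if arousal_lexicon is None:
        arousal_lexicon = resources.load_arousal_table()
    hits = [arousal_lexicon[w] for w in tt.unstemmed if w in arousal_lexicon]
    base = sum(hits) / len(hits) if hits else 0.0
    intensity = 1.0 - math.exp(-tt.emphasis.total / 2.0)
    return max(-1.0, min(1.0, base + emphasis_gain * intensity))


def tag_emotion(
    tweet_id: str,
    valence: float,
    arousal: float,
    cmap: Optional[CircumplexMap] = None,
    label: Optional[str] = None,
) -> EmotionTag:
    """Nearest-anchor assignment on the circumplex; ties break alphabetically.

    A tweet whose valence label is neutral keeps its nearest emotion but is
    assigned quadrant "neutral" and primary "none".
    """
    if cmap is None:
        cmap = CircumplexMap.default()
    if not (-1.0 <= valence <= 1.0 and -1.0 <= arousal <= 1.0):
        raise ValueError("valence and arousal must lie in [-1, 1]")
    best = min(
        sorted(cmap.anchors),
        key=lambda e: (
            (valence - cmap.anchors[e][0]) ** 2
            + (arousal - cmap.anchors[e][1]) ** 2,
            e,
        ),
    )
    if label == "neutral":
        return EmotionTag(tweet_id, valence, arousal, best, "neutral", "none")
    if valence > 0:
        quadrant = "highly_positive" if arousal >= 0 else "passive_positive"
    else:
        quadrant = "highly_negative" if arousal >= 0 else "subdued_negative"
    return EmotionTag(
        tweet_id, valence, arousal, best, quadrant, cmap.primary_of[best]
    )


def reduce_primary(emotion: str, cmap: Optional[CircumplexMap] = None) -> str:
    if cmap is None:
        cmap = CircumplexMap.default()
    if emotion not in cmap.primary_of:
        raise KeyError(f"unknown emotion {emotion!r}")
    return cmap.primary_of[emotion]


def aggregate_emotion_score(
    tags: Sequence[EmotionTag],
    weights: Optional[Sequence[float]] = None,
) -> dict[str, float]:
    """Linear combination of per-tweet emotion indicators: each tweet adds
    its weight (default uniform) to its primary emotion's mass; the result
    is normalized over the assigned (non-neutral) tweets."""
    if weights is None:
        weights = [1.0] * len(tags)
    if len(weights) != len(tags):
        raise ValueError("weights length mismatch")
    agg = {p: 0.0 for p in PRIMARIES}
    total = 0.0
    for tag, w in zip(tags, weights):
        if tag.primary == "none":
            continue
        agg[tag.primary] += w
        total += w
    if total == 0.0:
        import warnings

        warnings.warn("no assigned tweets; aggregate is all zeros")
        return agg
    return {p: m / total for p, m in agg.items()}


@dataclass
class NgramClassifier:
    """Uni+bigram frequency features into a linear max-margin classifier."""

    ngram_range: tuple[int, int] = (1, 2)
    seed: int = 0
    k_folds: int = 5
    pipeline: Optional[Pipeline] = None
    classes_: Optional[np.ndarray] = None
    prior_class: Optional[str] = None
    cv_macro_f: Optional[float] = None
    cv_fold_scores: list[float] = field(default_factory=list)

    def _docs(self, token_lists: Sequence[Sequence[str]]) -> list[str]:
        return [" ".join(toks) for toks in token_lists]

    def fit(
        self,
        token_lists: Sequence[Sequence[str]],
        labels: Sequence[str],
        cross_validate: bool = True,
    ) -> "NgramClassifier":
        labels = list(labels)
        if len(set(labels)) < 2:
            raise ValueError("training data must contain at least 2 classes")
        docs = self._docs(token_lists)
        self.pipeline = Pipeline(
            [
                ("ngrams", CountVectorizer(
                    ngram_range=self.ngram_range,
                    token_pattern=r"\S+",
                    lowercase=False,
                )),
                ("svm", LinearSVC(random_state=self.seed)),
            ]
        )
        if cross_validate:
            counts = {c: labels.count(c) for c in set(labels)}
            k = min(self.k_folds, min(counts.values()))
            cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=self.seed)
            scores = cross_val_score(
                self.pipeline, docs, labels, scoring="f1_macro", cv=cv
            )
            self.cv_fold_scores = [float(s) for s in scores]
            self.cv_macro_f = float(np.mean(scores))
        self.pipeline.fit(docs, labels)
        self.classes_ = self.pipeline.named_steps["svm"].classes_
        self.prior_class = max(set(labels), key=labels.count)
        return self

    def predict(
        self, token_lists: Sequence[Sequence[str]]
    ) -> tuple[list[str], list[bool]]:
        """Labels plus a per-tweet flag marking out-of-vocabulary-only
        inputs, which fall back to the training prior class."""
        if self.pipeline is None:
            raise RuntimeError("classifier is not trained")
        docs = self._docs(token_lists)
        X = self.pipeline.named_steps["ngrams"].transform(docs)
        oov = np.asarray(X.sum(axis=1)).ravel() == 0
        raw = self.pipeline.named_steps["svm"].predict(X)
        labels = [
            self.prior_class if is_oov else lab
            for lab, is_oov in zip(raw, oov)
        ]
        return labels, [bool(f) for f in oov]
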