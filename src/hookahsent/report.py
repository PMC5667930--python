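"""Corpus-level sentiment summaries and biased-vs-debiased comparison.

Conventions, stated once: percentages are rounded half-up at two decimals;
quadrant percentages are expressed within their parent label (e.g. the
share of positive tweets that are highly positive); and the five primary
emotion probabilities are computed over assigned (non-neutral) tweets only,
since neutral tweets carry no primary emotion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import pandas as pd

from .circumplex import PRIMARIES, QUADRANTS, EmotionTag

LABELS = ("positive", "negative", "neutral")

#: which quadrants report their share within which sentiment label
_QUADRANT_PARENT = {
    "highly_positive": "positive",
    "passive_positive": "positive",
    "subdued_negative": "negative",
    "highly_negative": "negative",
}


def pct(count: int, denom: int) -> float:
    """count/denom as a percentage, rounded half-up to 2 decimals."""
    if denom == 0:
        return 0.0
    return float(
        (Decimal(count) / Decimal(denom) * 100).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


@dataclass
class CorpusSummary:
    corpus_name: str
    n_tweets: int
    label_counts: dict[str, int]
    label_pcts: dict[str, float] = field(init=False)
    quadrant_counts: dict[str, int] = field(default_factory=dict)
    quadrant_pcts: dict[str, float] = field(init=False, default_factory=dict)
    primary_counts: dict[str, int] = field(default_factory=dict)
    primary_probs: dict[str, float] = field(init=False, default_factory=dict)

    def __post_init__(self):
        if self.n_tweets <= 0:
            raise ValueError("empty corpus has no summary")
        if sum(self.label_counts.values()) != self.n_tweets:
            raise ValueError("label counts do not sum to corpus size")
        self.label_pcts = {
            lab: pct(self.label_counts.get(lab, 0), self.n_tweets)
            for lab in LABELS
        }
        self.quadrant_pcts = {}
        for quad, parent in _QUADRANT_PARENT.items():
            if quad in self.quadrant_counts:
                self.quadrant_pcts[quad] = pct(
                    self.quadrant_counts[quad], self.label_counts.get(parent, 0)
                )
        n_assigned = sum(self.primary_counts.values())
        self.primary_probs = {
            p: pct(self.primary_counts.get(p, 0), n_assigned) for p in PRIMARIES
        } if n_assigned else {}

    def as_dict(self) -> dict:
        return {
            "corpus_name": self.corpus_name,
            "n_tweets": self.n_tweets,
            "label_counts": dict(self.label_counts),
            "label_pcts": dict(self.label_pcts),
            "quadrant_counts": dict(self.quadrant_counts),
            "quadrant_pcts": dict(self.quadrant_pcts),
            "primary_counts": dict(self.primary_counts),
            "primary_probs": dict(self.primary_probs),
        }


def summarize_counts(
    corpus_name: str,
    label_counts: dict[str, int],
    quadrant_counts: Optional[dict[str, int]] = None,
    primary_counts: Optional[dict[str, int]] = None,
) -> CorpusSummary:
    """Summary directly from count tables (the printed-table entry point)."""
    return CorpusSummary(
        corpus_name,
        sum(label_counts.values()),
        dict(label_counts),
        dict(quadrant_counts or {}),
        dict(primary_counts or {}),
    )


def summarize(
    corpus_name: str,
    labels: dict[str, str],
    tags: Sequence[EmotionTag],
) -> CorpusSummary:
    """Summary from per-tweet labels and emotion tags."""
    if not labels:
        raise ValueError("empty corpus has no summary")
    if set(labels) != {t.tweet_id for t in tags}:
        raise ValueError("labels and emotion tags cover different tweets")
    label_counts = {lab: 0 for lab in LABELS}
    for lab in labels.values():
        label_counts[lab] += 1
    quadrant_counts = {q: 0 for q in QUADRANTS}
    primary_counts = {p: 0 for p in PRIMARIES}
    for tag in tags:
        if tag.quadrant in quadrant_counts:
            quadrant_counts[tag.quadrant] += 1
        if tag.primary in primary_counts:
            primary_counts[tag.primary] += 1
    return summarize_counts(corpus_name, label_counts, quadrant_counts,
                            primary_counts)


@dataclass
class ComparisonTable:
    """Side-by-side primary-emotion probabilities, debiased vs biased."""

    emotions: tuple[str, ...]
    debiased: dict[str, float]
    biased: dict[str, float]
    deltas: dict[str, float] = field(init=False)

    def __post_init__(self):
        self.deltas = {
            e: round(self.debiased[e] - self.biased[e], 2) for e in self.emotions
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "emotion": list(self.emotions),
                "debiased_pct": [self.debiased[e] for e in self.emotions],
                "biased_pct": [self.biased[e] for e in self.emotions],
                "delta": [self.deltas[e] for e in self.emotions],
            }
        )

    def to_text(self) -> str:
        frame = self.to_frame()
        return frame.to_string(index=False)


def compare(
    summary_debiased: CorpusSummary, summary_biased: CorpusSummary
) -> ComparisonTable:
    """Per-primary-emotion probability comparison between two corpora."""
    a, b = summary_debiased.primary_probs, summary_biased.primary_probs
    if set(a) != set(b):
        raise ValueError("summaries cover different emotion sets")
    return ComparisonTable(tuple(PRIMARIES), dict(a), dict(b))
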