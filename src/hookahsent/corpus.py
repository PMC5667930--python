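"""Tweet/account data model, JSON-lines corpus I/O, and root-term filtering.

A corpus is a flat JSONL file: one header record carrying the schema version
and provenance, then one record per account and one per tweet, tagged by
``record_type``. Timestamps are ISO-8601 UTC on disk and epoch seconds in
memory.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

SCHEMA_VERSION = "1.0"

#: Collection window of the study corpus (UTC), inclusive.
WINDOW_START = datetime(2015, 3, 24, tzinfo=timezone.utc).timestamp()
WINDOW_END = datetime(2016, 12, 2, 23, 59, 59, tzinfo=timezone.utc).timestamp()

#: Root terms defining the topic corpus; each also matches with a plural "s"
#: and inside hashtags. "waterpipe" is deliberately absent: the term is
#: academic register and essentially unused in organic social-media posts.
DEFAULT_ROOT_TERMS = ("hookah", "hooka", "sheesha", "shisha", "sesh")


class ClientSource(str, Enum):
    MOBILE = "mobile"
    DESKTOP = "desktop"
    OTHER = "other"


class Provenance(str, Enum):
    RAW = "raw"
    DEBIASED = "debiased"
    BOTS_ONLY = "bots_only"
    MARKETING_ONLY = "marketing_only"


class CorpusValidationError(ValueError):
    """Raised when corpus invariants fail; carries the offending ids."""

    def __init__(self, message: str, ids: Optional[list[str]] = None):
        super().__init__(message)
        self.ids = ids or []


@dataclass(frozen=True)
class Tweet:
    tweet_id: str
    account_id: str
    timestamp: float  # UTC epoch seconds
    text: str
    source_client: ClientSource = ClientSource.OTHER
    is_retweet: bool = False
    mention_count: int = 0

    def __post_init__(self):
        if self.mention_count < 0:
            raise ValueError(f"mention_count < 0 for tweet {self.tweet_id}")


@dataclass
class Account:
    account_id: str
    followers: int = 0
    followees: int = 0
    tweet_ids: list[str] = field(default_factory=list)
    ground_truth_role: Optional[str] = None  # human | bot | marketing

    def __post_init__(self):
        if self.followers < 0 or self.followees < 0:
            raise ValueError(f"negative follower counts for {self.account_id}")


@dataclass
class Corpus:
    tweets: list[Tweet] = field(default_factory=list)
    accounts: dict[str, Account] = field(default_factory=dict)
    provenance: Provenance = Provenance.RAW
    truth: Optional[pd.DataFrame] = None  # sidecar ground truth (synthetic)
    n_malformed: int = 0  # lines rejected at read time

    def __len__(self) -> int:
        return len(self.tweets)

    def validate(self, strict_window: bool = False) -> None:
        seen: set[str] = set()
        dupes, orphans, out_of_window = [], [], []
        for t in self.tweets:
            if t.tweet_id in seen:
                dupes.append(t.tweet_id)
            seen.add(t.tweet_id)
            if t.account_id not in self.accounts:
                orphans.append(t.tweet_id)
            if strict_window and not (WINDOW_START <= t.timestamp <= WINDOW_END):
                out_of_window.append(t.tweet_id)
        if dupes:
            raise CorpusValidationError(f"duplicate tweet ids: {dupes[:5]}", dupes)
        if orphans:
            raise CorpusValidationError(
                f"tweets referencing missing accounts: {orphans[:5]}", orphans
            )
        if out_of_window:
            raise CorpusValidationError(
                f"timestamps outside collection window: {out_of_window[:5]}",
                out_of_window,
            )

    def subset(self, tweet_ids: Iterable[str], provenance: Provenance) -> "Corpus":
        """New corpus restricted to the given tweets; accounts re-derived."""
        keep = set(tweet_ids)
        tweets = [t for t in self.tweets if t.tweet_id in keep]
        used = {t.account_id for t in tweets}
        accounts = {}
        for aid in used:
            acc = self.accounts[aid]
            accounts[aid] = replace_account(acc, [i for i in acc.tweet_ids if i in keep])
        truth = None
        if self.truth is not None:
            truth = self.truth[self.truth["tweet_id"].isin(keep)].reset_index(drop=True)
        return Corpus(tweets, accounts, provenance, truth)


def replace_account(acc: Account, tweet_ids: list[str]) -> Account:
    return Account(acc.account_id, acc.followers, acc.followees, tweet_ids,
                   acc.ground_truth_role)


def _iso(ts: float) -> str:
    return datetime.fromtimestamp(ts, tz=timezone.utc).isoformat()


def _from_iso(s: str) -> float:
    return datetime.fromisoformat(s).timestamp()


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        header = {
            "record_type": "header",
            "schema_version": SCHEMA_VERSION,
            "provenance": corpus.provenance.value,
        }
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for acc in sorted(corpus.accounts.values(), key=lambda a: a.account_id):
            rec = {
                "record_type": "account",
                "account_id": acc.account_id,
                "followers": acc.followers,
                "followees": acc.followees,
                "tweet_ids": acc.tweet_ids,
            }
            if acc.ground_truth_role is not None:
                rec["ground_truth_role"] = acc.ground_truth_role
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
        for t in corpus.tweets:
            rec = {
                "record_type": "tweet",
                "tweet_id": t.tweet_id,
                "account_id": t.account_id,
                "timestamp": _iso(t.timestamp),
                "text": t.text,
                "source_client": t.source_client.value,
                "is_retweet": t.is_retweet,
                "mention_count": t.mention_count,
            }
            fh.write(json.dumps(rec, sort_keys=True, ensure_ascii=False) + "\n")


def read_corpus(
    path: str | Path,
    schema_version: str = SCHEMA_VERSION,
    strict_window: bool = False,
) -> Corpus:
    """Read a JSONL corpus; malformed lines are counted on the returned
    corpus (``n_malformed``), never silently dropped without trace.

    Raises ``CorpusValidationError`` if any tweet references a missing
    account, or (in strict mode) falls outside the collection window.
    """
    path = Path(path)
    corpus = Corpus()
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                rtype = rec["record_type"]
                if rtype == "header":
                    if rec["schema_version"] != schema_version:
                        raise CorpusValidationError(
                            f"schema version {rec['schema_version']!r} != "
                            f"expected {schema_version!r}"
                        )
                    corpus.provenance = Provenance(rec.get("provenance", "raw"))
                elif rtype == "account":
                    corpus.accounts[rec["account_id"]] = Account(
                        rec["account_id"],
                        int(rec.get("followers", 0)),
                        int(rec.get("followees", 0)),
                        list(rec.get("tweet_ids", [])),
                        rec.get("ground_truth_role"),
                    )
                elif rtype == "tweet":
                    corpus.tweets.append(
                        Tweet(
                            rec["tweet_id"],
                            rec["account_id"],
                            _from_iso(rec["timestamp"]),
                            rec["text"],
                            ClientSource(rec.get("source_client", "other")),
                            bool(rec.get("is_retweet", False)),
                            int(rec.get("mention_count", 0)),
                        )
                    )
                else:
                    corpus.n_malformed += 1
            except CorpusValidationError:
                raise
            except (KeyError, ValueError, TypeError):
                corpus.n_malformed += 1
    corpus.validate(strict_window=strict_window)
    return corpus


def _root_term_pattern(root_terms: Iterable[str]) -> re.Pattern:
    alts = "|".join(re.escape(t) for t in root_terms)
    # token-boundary aware; "s" plural expansion; matches inside "#hookah"
    return re.compile(rf"(?<![a-z0-9])(?:{alts})s?(?![a-z0-9])", re.IGNORECASE)


def keyword_filter(corpus: Corpus, root_terms: Iterable[str] = DEFAULT_ROOT_TERMS) -> Corpus:
    """Keep only tweets whose text (or hashtags) mention a root term.

    Matching is case-insensitive, token-boundary aware, with plural-"s"
    expansion: "hookah" matches "#hookah" and "hookahs" but not "hook".
    """
    terms = list(root_terms)
    if not terms:
        raise ValueError("root_terms must be non-empty")
    pat = _root_term_pattern(terms)
    keep = [t.tweet_id for t in corpus.tweets if pat.search(t.text)]
    return corpus.subset(keep, corpus.provenance)
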