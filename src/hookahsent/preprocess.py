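"""Tweet text preparation: tokenization, normalization, and coarse POS tags.

The pipeline is three explicit stages, run in order:

1. ``tokenize`` — strip URLs and HTML, count emphasis (exclamations,
   ALL-CAPS tokens) on the raw surface form, then drop stop words.
2. ``normalize`` — unify emoticons into SMILE/FROWN sentinels, unify
   contraction spellings ("don't"/"dont"), compress elongated character runs
   ("grrrrrreat" -> "great") against the package dictionary, expand slang,
   and Porter-stem last.
3. ``pos_tag`` — coarse six-way tags (noun/verb/adjective/adverb/
   preposition/other) from a small tag lexicon plus suffix rules; only
   noun/verb/adverb rates are consumed downstream (bot content features).

Emphasis is always counted before lowercasing and stop-word removal, so the
emphasis record is invariant to those steps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from . import resources
from .stemmer import stem

_HTML_RE = re.compile(r"<[^>]+>")
_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_BARE_DOMAIN_RE = re.compile(r"\b\S+\.(?:com|net|org|co|io|ly)(?:/\S*)?(?=\s|$)")

_SMILES = {":)", ":-)", ":]", "=)", ":d", ":-d", ";)", ";-)", "^_^", "☺"}
_FROWNS = {":(", ":-(", ":[", "=(", ":'(", "d:", "☹"}
_EMOTICON_RE = re.compile(
    r"(?:\^_\^|:'\(|[:;=][-']?[)(\]\[dD]|[☺☹])"
)
_WORD_RE = re.compile(r"[#@]?[A-Za-z0-9_']+")
_TOKEN_RE = re.compile(_EMOTICON_RE.pattern + "|" + _WORD_RE.pattern)

SMILE, FROWN = "SMILE", "FROWN"


@dataclass
class Emphasis:
    allcaps_token_count: int = 0
    exclamation_count: int = 0
    elongation_count: int = 0
    emoticon_class_counts: dict[str, int] = field(
        default_factory=lambda: {"smile": 0, "frown": 0}
    )

    @property
    def total(self) -> int:
        return (
            self.allcaps_token_count
            + self.exclamation_count
            + self.elongation_count
        )


@dataclass
class TokenStream:
    """Raw tokens with surface case preserved, plus per-token clause flags."""

    tokens: list[str]
    exclaimed: list[bool]  # token sits in a clause terminated by "!"
    emphasis: Emphasis


@dataclass
class TokenizedTweet:
    tweet_id: str
    tokens: list[str]          # normalized + stemmed
    unstemmed: list[str]       # normalized, pre-stemming (lexicon lookup keys)
    raw: list[str]             # surface form, case preserved
    pos_tags: list[str]
    emphasis: Emphasis
    allcaps: list[bool]
    exclaimed: list[bool]

    def __post_init__(self):
        n = len(self.tokens)
        assert len(self.pos_tags) == n and len(self.unstemmed) == n


def tokenize(text: str, stopwords: frozenset[str] | None = None) -> TokenStream:
    """Split cleaned text into tokens and count surface emphasis.

    URLs (scheme-prefixed, www-prefixed, and trailing bare domains) are
    removed; HTML tags become whitespace; undecodable replacement characters
    are dropped. Exclamation and ALL-CAPS counts are taken before any
    lowercasing; stop words are removed after.
    """
    if stopwords is None:
        stopwords = resources.load_wordset("stopwords")
    emphasis = Emphasis()
    text = text.replace("’", "'").replace("�", "")
    text = _HTML_RE.sub(" ", text)
    text = _URL_RE.sub(" ", text)
    text = _BARE_DOMAIN_RE.sub(" ", text)
    emphasis.exclamation_count = text.count("!")

    tokens: list[str] = []
    exclaimed: list[bool] = []
    # clause segmentation: a token is "exclaimed" if its clause ends with "!"
    for clause in re.split(r"(?<=[.!?])\s+|\n", text):
        bang = clause.rstrip().endswith("!") or "!" in clause
        for tok in _TOKEN_RE.findall(clause):
            core = tok.lstrip("#@")
            if tok.startswith("@"):
                continue  # mentions carry no sentiment
            if core.isalpha() and core.isupper() and len(core) >= 2:
                emphasis.allcaps_token_count += 1
            if core.lower().replace("'", "") in stopwords or core.lower() in stopwords:
                continue
            tokens.append(tok)
            exclaimed.append(bang)
    return TokenStream(tokens, exclaimed, emphasis)


def _unelongate(word: str, vocab: frozenset[str]) -> tuple[str, bool]:
    """Compress character runs of length >= 3 to the shortest dictionary-
    valid form; if none validates, runs collapse to length 2."""
    runs = list(re.finditer(r"(.)\1{2,}", word))
    if not runs:
        return word, False
    # candidate run lengths 1 or 2 per run, shortest total first
    candidates = []
    n_runs = len(runs)
    for mask in sorted(range(2 ** n_runs), key=lambda m: bin(m).count("1")):
        out, last = [], 0
        for i, m in enumerate(runs):
            out.append(word[last : m.start()])
            out.append(m.group(1) * (1 + ((mask >> i) & 1)))
            last = m.end()
        out.append(word[last:])
        candidates.append("".join(out))
    for cand in candidates:
        if cand in vocab:
            return cand, True
    return candidates[-1], True  # all runs at length 2


def normalize(stream: TokenStream) -> tuple[list[str], list[str], list[bool], list[bool]]:
    """Normalize raw tokens; returns (unstemmed, stemmed, allcaps, exclaimed)
    parallel lists and updates the stream's emphasis record in place."""
    vocab = resources.dictionary()
    slang = resources.load_tsv_map("slang")
    unstemmed: list[str] = []
    stemmed: list[str] = []
    allcaps: list[bool] = []
    exclaimed: list[bool] = []
    for tok, bang in zip(stream.tokens, stream.exclaimed):
        core = tok.lstrip("#")
        if core in (SMILE, FROWN):  # already-normalized sentinel
            unstemmed.append(core)
            stemmed.append(core)
            allcaps.append(False)
            exclaimed.append(bang)
            continue
        if _EMOTICON_RE.fullmatch(core) or core.lower() in _SMILES | _FROWNS:
            cls = "smile" if core.lower() in _SMILES else "frown"
            stream.emphasis.emoticon_class_counts[cls] += 1
            unstemmed.append(SMILE if cls == "smile" else FROWN)
            stemmed.append(SMILE if cls == "smile" else FROWN)
            allcaps.append(False)
            exclaimed.append(bang)
            continue
        caps = core.isalpha() and core.isupper() and len(core) >= 2
        w = core.lower().replace("'", "")
        w, elong = _unelongate(w, vocab)
        if elong:
            stream.emphasis.elongation_count += 1
        w = slang.get(w, w)
        if not w:
            continue
        unstemmed.append(w)
        stemmed.append(stem(w))
        allcaps.append(caps)
        exclaimed.append(bang)
    return unstemmed, stemmed, allcaps, exclaimed


_PREPOSITIONS = frozenset(
    "in on at by for with from to of over under near between through".split()
)
_SUFFIX_RULES = (
    ("ly", "adverb"),
    ("ing", "verb"),
    ("ed", "verb"),
    ("tion", "noun"),
    ("ness", "noun"),
    ("ment", "noun"),
    ("ful", "adjective"),
    ("ous", "adjective"),
    ("ive", "adjective"),
    ("able", "adjective"),
    ("ish", "adjective"),
)


def pos_tag(unstemmed_tokens: list[str]) -> list[str]:
    """Coarse tags from the shipped tag lexicon, then suffix rules; unknown
    words tag as ``other``."""
    lex = resources.load_tsv_map("pos_lexicon")
    tags = []
    for tok in unstemmed_tokens:
        if tok in (SMILE, FROWN) or not tok.isalpha():
            tags.append("other")
            continue
        if tok in lex:
            tags.append(lex[tok])
            continue
        if tok in _PREPOSITIONS:
            tags.append("preposition")
            continue
        for suf, tag in _SUFFIX_RULES:
            if tok.endswith(suf) and len(tok) > len(suf) + 2:
                tags.append(tag)
                break
        else:
            tags.append("other")
    return tags


def preprocess_tweet(tweet_id: str, text: str) -> TokenizedTweet:
    """Full preparation pipeline for one tweet."""
    stream = tokenize(text)
    unstemmed, stemmed, allcaps, exclaimed = normalize(stream)
    tags = pos_tag(unstemmed)
    return TokenizedTweet(
        tweet_id=tweet_id,
        tokens=stemmed,
        unstemmed=unstemmed,
        raw=list(stream.tokens),
        pos_tags=tags,
        emphasis=stream.emphasis,
        allcaps=allcaps,
        exclaimed=exclaimed,
    )
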