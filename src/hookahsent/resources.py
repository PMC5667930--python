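"""Loaders for the word-list and lexicon data files shipped with the package.

All lexica are plain text: one entry per line, tab-separated columns where a
value is attached. Users can point any loader at their own file to swap a
resource out.
"""

from __future__ import annotations

from functools import lru_cache
from pathlib import Path

DATA_DIR = Path(__file__).parent / "data"


def _lines(path: Path) -> list[str]:
    out = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


@lru_cache(maxsize=None)
def load_wordset(name: str, path: str | None = None) -> frozenset[str]:
    p = Path(path) if path else DATA_DIR / f"{name}.txt"
    return frozenset(w.lower() for w in _lines(p))


@lru_cache(maxsize=None)
def load_tsv_map(name: str, path: str | None = None) -> dict[str, str]:
    p = Path(path) if path else DATA_DIR / f"{name}.tsv"
    out: dict[str, str] = {}
    for line in _lines(p):
        key, val = line.split("\t")[:2]
        out[key] = val
    return out


@lru_cache(maxsize=None)
def load_valence_table(path: str | None = None) -> dict[str, float]:
    p = Path(path) if path else DATA_DIR / "valence_lexicon.tsv"
    return {k: float(v) for k, v in load_tsv_map("valence_lexicon", str(p)).items()}


@lru_cache(maxsize=None)
def load_arousal_table(path: str | None = None) -> dict[str, float]:
    p = Path(path) if path else DATA_DIR / "arousal_lexicon.tsv"
    return {k: float(v) for k, v in load_tsv_map("arousal_lexicon", str(p)).items()}


@lru_cache(maxsize=None)
def load_spam_phrases() -> tuple[str, ...]:
    return tuple(p.lower() for p in _lines(DATA_DIR / "spam_phrases.txt"))


@lru_cache(maxsize=None)
def load_marketing_keywords() -> tuple[str, ...]:
    return tuple(p.lower() for p in _lines(DATA_DIR / "marketing_keywords.txt"))


@lru_cache(maxsize=None)
def dictionary() -> frozenset[str]:
    """Union of all shipped word lists; the reference vocabulary used when
    un-elongating character runs ("grrrrrreat" -> "great")."""
    words: set[str] = set()
    words |= {w.lower() for w in load_valence_table() if w.isalpha()}
    words |= set(load_arousal_table())
    words |= set(load_tsv_map("pos_lexicon"))
    words |= set(load_wordset("stopwords"))
    words |= set(load_wordset("boosters"))
    words |= set(load_wordset("negators"))
    words |= set(load_wordset("contrast"))
    words |= set(load_tsv_map("slang").values())
    return frozenset(words)
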