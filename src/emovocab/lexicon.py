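"""Emotion lexicon and auxiliary word lists.

The emotion lexicon is a closed vocabulary of words that primarily *name*
emotional states, each entry carrying a valence (negative/positive), an
emotion family (sadness, fear, anger, undifferentiated_negative, positive)
and a lemma group: inflectional variants such as *sad*, *sadness*, *sadly*
share one lemma group and therefore count as a single emotion word when
vocabulary diversity is measured.

Entries are either literal lowercase tokens or prefix-wildcard stems written
with a trailing asterisk (``furi*`` matches any token starting with
``furi``), mirroring the word-stem convention of count-based text-analysis
dictionaries. Lemma collapsing is encoded explicitly in the dictionary file
rather than by algorithmic stemming, so the mapping is auditable.

Canonical dictionary dialect: UTF-8 TSV with header
``pattern\tvalence\tfamily\tlemma_group``; ``#``-prefixed lines are comments.
Word lists (function words; coverage vocabulary; category lists) are one
lowercase token per line.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Union

__all__ = [
    "NEGATIVE",
    "POSITIVE",
    "VALENCES",
    "NEGATIVE_FAMILIES",
    "FAMILIES",
    "LexiconEntry",
    "EmotionLexicon",
    "WordList",
    "LexiconError",
    "Match",
    "load_lexicon",
    "load_wordlist",
    "match_token",
    "packaged_lexicon",
    "packaged_function_words",
    "packaged_coverage_vocabulary",
    "packaged_category",
    "packaged_category_names",
]

NEGATIVE = "negative"
POSITIVE = "positive"
VALENCES = (NEGATIVE, POSITIVE)
NEGATIVE_FAMILIES = ("sadness", "fear", "anger", "undifferentiated_negative")
FAMILIES = NEGATIVE_FAMILIES + ("positive",)

_DATA_PKG = "emovocab.data"


class LexiconError(ValueError):
    """Raised when a dictionary or word-list file violates its invariants."""


class Match(NamedTuple):
    """Result of matching one token against the lexicon."""

    lemma_group: str
    valence: str
    family: str


@dataclass(frozen=True)
class LexiconEntry:
    """One dictionary row: a token pattern with its emotion classification."""

    pattern: str
    valence: str
    family: str
    lemma_group: str

    def __post_init__(self) -> None:
        p = self.pattern
        if not p:
            raise LexiconError("empty pattern")
        if p != p.lower():
            raise LexiconError(f"pattern not lowercase: {p!r}")
        if p.count("*") > 1 or ("*" in p and not p.endswith("*")):
            raise LexiconError(f"malformed wildcard in pattern {p!r}")
        if p == "*":
            raise LexiconError("bare '*' pattern matches everything")
        if self.valence not in VALENCES:
            raise LexiconError(f"unknown valence {self.valence!r}")
        if self.family not in FAMILIES:
            raise LexiconError(f"unknown family {self.family!r}")
        if (self.family == "positive") != (self.valence == POSITIVE):
            raise LexiconError(
                f"family/valence mismatch for {p!r}: "
                f"{self.family}/{self.valence}"
            )
        if not self.lemma_group:
            raise LexiconError(f"empty lemma_group for pattern {p!r}")

    @property
    def is_wildcard(self) -> bool:
        return self.pattern.endswith("*")

    @property
    def prefix(self) -> str:
        """The literal prefix of a wildcard pattern (pattern sans ``*``)."""
        return self.pattern[:-1] if self.is_wildcard else self.pattern


@dataclass
class EmotionLexicon:
    """A validated emotion dictionary with fast token matching.

    Literal patterns take precedence over wildcard stems; among wildcard
    stems that match, the longest prefix wins. Matching is deterministic
    and total over lowercase tokens (no match is a normal outcome).
    """

    entries: list[LexiconEntry]
    name: str = "emotion_lexicon"
    version: str = "0"
    _literals: dict[str, LexiconEntry] = field(
        init=False, repr=False, compare=False)
    _prefixes: list[tuple[str, LexiconEntry]] = field(
        init=False, repr=False, compare=False)
    _group_forms: dict[str, list[str]] = field(
        init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._validate()
        self._literals = {
            e.pattern: e for e in self.entries if not e.is_wildcard}
        self._prefixes = sorted(
            ((e.prefix, e) for e in self.entries if e.is_wildcard),
            key=lambda t: len(t[0]),
            reverse=True,
        )
        self._group_forms = {}
        for e in self.entries:
            if not e.is_wildcard:
                self._group_forms.setdefault(e.lemma_group, []).append(
                    e.pattern)

    def _validate(self) -> None:
        seen: dict[str, LexiconEntry] = {}
        group_info: dict[str, tuple[str, str]] = {}
        for e in self.entries:
            if e.pattern in seen:
                raise LexiconError(f"duplicate pattern {e.pattern!r}")
            seen[e.pattern] = e
            info = (e.valence, e.family)
            prev = group_info.setdefault(e.lemma_group, info)
            if prev != info:
                raise LexiconError(
                    f"lemma_group {e.lemma_group!r} spans "
                    f"{prev} and {info}"
                )

    # -- queries ---------------------------------------------------------

    def match(self, token: str) -> Optional[Match]:
        """Match one case-folded token; ``None`` when nothing matches."""
        entry = self._literals.get(token)
        if entry is None:
            for prefix, cand in self._prefixes:
                if token.startswith(prefix):
                    entry = cand
                    break
            else:
                return None
        return Match(entry.lemma_group, entry.valence, entry.family)

    def lemma_groups(self, valence: Optional[str] = None,
                     family: Optional[str] = None) -> list[str]:
        """Distinct lemma groups, in first-appearance order, optionally
        restricted to one valence or family."""
        out: list[str] = []
        seen: set[str] = set()
        for e in self.entries:
            if valence is not None and e.valence != valence:
                continue
            if family is not None and e.family != family:
                continue
            if e.lemma_group not in seen:
                seen.add(e.lemma_group)
                out.append(e.lemma_group)
        return out

    def surface_forms(self, lemma_group: str) -> list[str]:
        """Literal (non-wildcard) patterns belonging to one lemma group."""
        return list(self._group_forms.get(lemma_group, []))

    def slice(self, valence: str) -> "EmotionLexicon":
        """A sub-lexicon restricted to one valence (used as a frequency
        category, e.g. emotional tone)."""
        if valence not in VALENCES:
            raise LexiconError(f"unknown valence {valence!r}")
        return EmotionLexicon(
            entries=[e for e in self.entries if e.valence == valence],
            name=f"{self.name}:{valence}",
            version=self.version,
        )

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class WordList:
    """A flat set of literal lowercase tokens with a declared role."""

    words: frozenset[str]
    role: str = "coverage_vocabulary"
    name: str = "wordlist"

    def __post_init__(self) -> None:
        if not self.words:
            raise LexiconError(f"word list {self.name!r} is empty")
        bad = [w for w in self.words if not w or w != w.lower()]
        if bad:
            raise LexiconError(
                f"word list {self.name!r} has non-lowercase entries: "
                f"{sorted(bad)[:5]}"
            )

    def __contains__(self, token: str) -> bool:
        return token in self.words

    def __len__(self) -> int:
        return len(self.words)


# -- loading ------------------------------------------------------------

Source = Union[str, Path, io.TextIOBase]


def _read_lines(source: Source) -> list[str]:
    if isinstance(source, io.TextIOBase):
        return source.read().splitlines()
    if isinstance(source, str) and ("\n" in source or "\t" in source):
        return source.splitlines()  # inline content
    path = Path(source)
    if path.exists():
        return path.read_text(encoding="utf-8").splitlines()
    raise FileNotFoundError(f"no such dictionary file: {source}")


def load_lexicon(source: Source, name: str = "emotion_lexicon",
                 version: str = "1.0") -> EmotionLexicon:
    """Parse and validate a dictionary in the canonical TSV dialect.

    ``source`` may be a file path, an open text stream, or the TSV content
    itself. Entry order is preserved. Raises :class:`LexiconError` on
    duplicate patterns, family/valence mismatches or malformed wildcards.
    """
    header = ["pattern", "valence", "family", "lemma_group"]
    entries: list[LexiconEntry] = []
    saw_header = False
    for lineno, line in enumerate(_read_lines(source), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if not saw_header:
            if [f.strip() for f in fields] != header:
                raise LexiconError(
                    f"line {lineno}: expected header {header}, got {fields}")
            saw_header = True
            continue
        if len(fields) != 4:
            raise LexiconError(
                f"line {lineno}: expected 4 tab-separated fields, "
                f"got {len(fields)}"
            )
        entries.append(LexiconEntry(*[f.strip() for f in fields]))
    if not saw_header:
        raise LexiconError("missing header line")
    if not entries:
        raise LexiconError("dictionary has no entries")
    return EmotionLexicon(entries=entries, name=name, version=version)


def load_wordlist(source: Source, role: str = "coverage_vocabulary",
                  name: str = "wordlist") -> WordList:
    """Load a one-token-per-line word list (``#`` comments ignored)."""
    words = set()
    for line in _read_lines(source):
        w = line.strip()
        if w and not w.startswith("#"):
            words.add(w)
    return WordList(words=frozenset(words), role=role, name=name)


def match_token(lexicon: EmotionLexicon, token: str) -> Optional[Match]:
    """Functional form of :meth:`EmotionLexicon.match`."""
    return lexicon.match(token)


# -- packaged resources --------------------------------------------------

def _data_text(*parts: str) -> str:
    node = resources.files(_DATA_PKG)
    for p in parts:
        node = node / p
    return node.read_text(encoding="utf-8")


def packaged_lexicon() -> EmotionLexicon:
    """The demonstration emotion dictionary shipped with the package.

    Counting lemma headwords it contains 92 negative and 53 positive
    emotion words; additional rows are inflected surface forms and
    wildcard stems within those lemma groups.
    """
    return load_lexicon(
        io.StringIO(_data_text("emotion_lexicon.tsv")),
        name="emovocab_demo", version="1.0",
    )


def packaged_function_words() -> WordList:
    return load_wordlist(
        io.StringIO(_data_text("function_words.txt")),
        role="function_words", name="emovocab_function_words",
    )


def packaged_coverage_vocabulary() -> WordList:
    return load_wordlist(
        io.StringIO(_data_text("coverage_vocabulary.txt")),
        role="coverage_vocabulary", name="emovocab_coverage",
    )


def packaged_category_names() -> list[str]:
    files = resources.files(_DATA_PKG) / "categories"
    return sorted(
        p.name[:-4] for p in files.iterdir() if p.name.endswith(".txt"))


def packaged_category(name: str) -> WordList:
    """One of the demonstration frequency-category word lists."""
    return load_wordlist(
        io.StringIO(_data_text("categories", f"{name}.txt")),
        role="category", name=name,
    )
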