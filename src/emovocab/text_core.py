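"""Tokenization, case folding, document screening, and corpus readers.

Tokenizer convention: text is Unicode-lowercased, curly apostrophes are
normalized to ASCII, and tokens are maximal runs of letters optionally
joined by internal apostrophes, so contractions ("don't") are single
tokens. Hyphenated compounds split into their constituents, punctuation is
stripped, and digit-only strings are dropped. Under this convention the
clause "he was so angry at me, but sadly there was nothing I could do" has
14 tokens and "A horse! A horse! My Kingdom for a horse!" has 9.

Screening mirrors the analyzability criteria of naturalistic writing
studies: a document is retained when it has at least ``min_tokens`` words
and at least ``min_coverage`` of them are identifiable against a common
vocabulary (defaults 100 words, 70%).
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

from .lexicon import WordList

__all__ = [
    "TokenizedDocument",
    "ScreeningResult",
    "tokenize",
    "screen_document",
    "read_corpus",
    "read_text_directory",
]

# letters (any script) optionally joined by internal ASCII apostrophes;
# \d and _ excluded so "2023" drops and "a_b" splits
_TOKEN_RE = re.compile(r"[^\W\d_]+(?:'[^\W\d_]+)*")
_APOSTROPHES = str.maketrans({"’": "'", "‘": "'",
                              "ʼ": "'", "`": "'", "´": "'"})


@dataclass(frozen=True)
class TokenizedDocument:
    """Ordered lowercase word tokens for one document."""

    doc_id: str
    tokens: tuple[str, ...]
    token_count: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.token_count == -1:
            object.__setattr__(self, "token_count", len(self.tokens))
        elif self.token_count != len(self.tokens):
            raise ValueError(
                f"token_count {self.token_count} != len(tokens) "
                f"{len(self.tokens)}"
            )

    @property
    def text(self) -> str:
        return " ".join(self.tokens)


@dataclass(frozen=True)
class ScreeningResult:
    """Inclusion decision for one document with the reasons for exclusion."""

    doc_id: str
    included: bool
    token_count: int
    coverage: float
    reasons: tuple[str, ...]


def tokenize(raw: str, doc_id: str = "") -> TokenizedDocument:
    """Case-fold and tokenize raw text into a :class:`TokenizedDocument`.

    Idempotent on its own output rejoined by spaces.
    """
    norm = unicodedata.normalize("NFC", raw).translate(_APOSTROPHES).lower()
    tokens = tuple(_TOKEN_RE.findall(norm))
    return TokenizedDocument(doc_id=doc_id, tokens=tokens)


def screen_document(doc: TokenizedDocument, coverage_vocab: WordList,
                    min_tokens: int = 100,
                    min_coverage: float = 0.70) -> ScreeningResult:
    """Apply the analyzability screen to one tokenized document.

    ``coverage`` is the fraction of tokens present in ``coverage_vocab``
    (0 for an empty document). The document is included iff it meets both
    the length and the coverage criterion; every failed criterion is
    listed in ``reasons``.
    """
    if coverage_vocab.role != "coverage_vocabulary":
        raise ValueError(
            f"coverage_vocab must have role 'coverage_vocabulary', "
            f"got {coverage_vocab.role!r}"
        )
    n = doc.token_count
    covered = sum(1 for t in doc.tokens if t in coverage_vocab)
    coverage = covered / n if n else 0.0
    reasons: list[str] = []
    if n < min_tokens:
        reasons.append(f"token_count<{min_tokens}")
    if coverage < min_coverage:
        reasons.append(f"coverage<{min_coverage:.2f}")
    return ScreeningResult(
        doc_id=doc.doc_id, included=not reasons, token_count=n,
        coverage=coverage, reasons=tuple(reasons),
    )


def read_corpus(source: Union[str, Path, pd.DataFrame],
                sep: str | None = None) -> pd.DataFrame:
    """Read a corpus table with required columns ``doc_id`` and ``text``.

    Accepts a CSV/TSV path (delimiter inferred from the extension unless
    ``sep`` is given) or an existing DataFrame. All other columns are
    carried through as per-author covariates. ``doc_id`` is coerced to
    string and must be unique.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        path = Path(source)
        if sep is None:
            sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        df = pd.read_csv(path, sep=sep, dtype={"doc_id": str})
    missing = {"doc_id", "text"} - set(df.columns)
    if missing:
        raise ValueError(f"corpus table missing columns: {sorted(missing)}")
    df["doc_id"] = df["doc_id"].astype(str)
    if df["doc_id"].duplicated().any():
        dups = df.loc[df["doc_id"].duplicated(), "doc_id"].tolist()[:5]
        raise ValueError(f"duplicate doc_id values: {dups}")
    return df.reset_index(drop=True)


def read_text_directory(directory: Union[str, Path]) -> pd.DataFrame:
    """Read one document per ``.txt`` file; doc_id is the filename stem."""
    directory = Path(directory)
    rows = [
        {"doc_id": p.stem, "text": p.read_text(encoding="utf-8")}
        for p in sorted(directory.glob("*.txt"))
    ]
    if not rows:
        raise ValueError(f"no .txt files in {directory}")
    return pd.DataFrame(rows)
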