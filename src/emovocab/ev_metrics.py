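"""Per-document lexical metrics.

Two complementary ways of counting emotion words:

* **Emotion vocabulary (EV)** is diversity-based: the number of *unique*
  emotion words — unique at the lemma-group level, so *sad*, *sadness* and
  *sadly* together contribute one — expressed per 100 tokens::

      EV = (unique emotion words / total word count) * 100

  Family-specific EVs apply the same formula to one emotion family
  (sadness, fear, anger, undifferentiated negative, positive).

* **Category rates** are frequency-based: the percentage of tokens (with
  repetition) belonging to a category, the counting convention of
  closed-vocabulary word-count tools. A text repeating one emotion word
  ten times and a text using ten different emotion words get the same
  frequency score but very different EV scores.

The type/token ratio (TTR) is reported both raw and in an open-class
variant that removes function words and all emotion-lexicon matches from
numerator and denominator alike, leaving a general-vocabulary index that
cannot be confounded with the EV numerator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

from .lexicon import (
    EmotionLexicon,
    NEGATIVE,
    NEGATIVE_FAMILIES,
    FAMILIES,
    POSITIVE,
    VALENCES,
    WordList,
)
from .text_core import TokenizedDocument

__all__ = [
    "EVScores",
    "CategoryRates",
    "TTRScore",
    "EmptyDocumentError",
    "ev_score",
    "unique_lemma_groups",
    "family_ev_scores",
    "score_ev",
    "category_rate",
    "ttr",
    "score_document",
    "write_score_table",
]

Category = Union[WordList, EmotionLexicon]


class EmptyDocumentError(ValueError):
    """Raised when a rate is requested for a zero-token document."""


@dataclass(frozen=True)
class EVScores:
    """Diversity-based emotion-vocabulary rates for one document."""

    doc_id: str
    neg_ev: float
    pos_ev: float
    family_ev: Mapping[str, float]
    unique_neg: int
    unique_pos: int
    token_count: int


@dataclass(frozen=True)
class CategoryRates:
    """Frequency-based category percentages (repeats counted)."""

    doc_id: str
    rates: Mapping[str, float]


@dataclass(frozen=True)
class TTRScore:
    """Raw and open-class type/token ratios, as percentages.

    ``open_class_ttr`` is ``None`` (and ``all_function_words`` True) when
    no open-class, non-emotion tokens remain.
    """

    doc_id: str
    raw_ttr: float
    open_class_ttr: Optional[float]
    all_function_words: bool = False


def _require_nonempty(doc: TokenizedDocument) -> None:
    if doc.token_count == 0:
        raise EmptyDocumentError(f"empty document {doc.doc_id!r}")


def unique_lemma_groups(doc: TokenizedDocument, lexicon: EmotionLexicon,
                        valence: Optional[str] = None,
                        family: Optional[str] = None) -> set[str]:
    """Distinct emotion lemma groups matched anywhere in the document."""
    groups: set[str] = set()
    for token in doc.tokens:
        m = lexicon.match(token)
        if m is None:
            continue
        if valence is not None and m.valence != valence:
            continue
        if family is not None and m.family != family:
            continue
        groups.add(m.lemma_group)
    return groups


def ev_score(doc: TokenizedDocument, lexicon: EmotionLexicon,
             valence: str) -> float:
    """Emotion-vocabulary rate for one valence, per 100 tokens."""
    if valence not in VALENCES:
        raise ValueError(f"unknown valence {valence!r}")
    _require_nonempty(doc)
    unique = len(unique_lemma_groups(doc, lexicon, valence=valence))
    return 100.0 * unique / doc.token_count


def family_ev_scores(doc: TokenizedDocument,
                     lexicon: EmotionLexicon) -> dict[str, float]:
    """EV rate per emotion family, per 100 tokens."""
    _require_nonempty(doc)
    counts: dict[str, set[str]] = {f: set() for f in FAMILIES}
    for token in doc.tokens:
        m = lexicon.match(token)
        if m is not None:
            counts[m.family].add(m.lemma_group)
    return {f: 100.0 * len(g) / doc.token_count for f, g in counts.items()}


def score_ev(doc: TokenizedDocument, lexicon: EmotionLexicon) -> EVScores:
    """Full EV bundle: valence EVs, family EVs and unique counts."""
    _require_nonempty(doc)
    fam = family_ev_scores(doc, lexicon)
    neg_groups = unique_lemma_groups(doc, lexicon, valence=NEGATIVE)
    pos_groups = unique_lemma_groups(doc, lexicon, valence=POSITIVE)
    return EVScores(
        doc_id=doc.doc_id,
        neg_ev=100.0 * len(neg_groups) / doc.token_count,
        pos_ev=100.0 * len(pos_groups) / doc.token_count,
        family_ev=fam,
        unique_neg=len(neg_groups),
        unique_pos=len(pos_groups),
        token_count=doc.token_count,
    )


def category_rate(doc: TokenizedDocument, category: Category) -> float:
    """Frequency-based percentage of tokens matching a category.

    ``category`` is either a flat :class:`WordList` or an
    :class:`EmotionLexicon` (typically a valence slice, e.g. emotional
    tone); repetitions count.
    """
    _require_nonempty(doc)
    if isinstance(category, EmotionLexicon):
        hits = sum(1 for t in doc.tokens if category.match(t) is not None)
    else:
        hits = sum(1 for t in doc.tokens if t in category)
    return 100.0 * hits / doc.token_count


def ttr(doc: TokenizedDocument, function_words: WordList,
        lexicon: EmotionLexicon) -> TTRScore:
    """Raw and open-class type/token ratios for one document."""
    _require_nonempty(doc)
    if function_words.role != "function_words":
        raise ValueError(
            f"function_words must have role 'function_words', "
            f"got {function_words.role!r}"
        )
    raw = 100.0 * len(set(doc.tokens)) / doc.token_count
    open_tokens = [
        t for t in doc.tokens
        if t not in function_words and lexicon.match(t) is None
    ]
    if not open_tokens:
        return TTRScore(doc_id=doc.doc_id, raw_ttr=raw,
                        open_class_ttr=None, all_function_words=True)
    oc = 100.0 * len(set(open_tokens)) / len(open_tokens)
    return TTRScore(doc_id=doc.doc_id, raw_ttr=raw, open_class_ttr=oc)


def score_document(doc: TokenizedDocument, lexicon: EmotionLexicon,
                   function_words: WordList,
                   categories: Mapping[str, Category] | None = None,
                   ) -> dict[str, object]:
    """One flat score row for a document: EVs, TTRs and category rates."""
    ev = score_ev(doc, lexicon)
    t = ttr(doc, function_words, lexicon)
    row: dict[str, object] = {
        "doc_id": doc.doc_id,
        "token_count": doc.token_count,
        "neg_ev": ev.neg_ev,
        "pos_ev": ev.pos_ev,
        "unique_neg": ev.unique_neg,
        "unique_pos": ev.unique_pos,
        "raw_ttr": t.raw_ttr,
        "open_class_ttr": t.open_class_ttr,
    }
    for fam in FAMILIES:
        row[f"ev_{fam}"] = ev.family_ev[fam]
    for name, cat in (categories or {}).items():
        row[name] = category_rate(doc, cat)
    return row


def write_score_table(scores: pd.DataFrame,
                      path: Union[str, Path]) -> None:
    """Write the per-document score table as TSV."""
    scores.to_csv(path, sep="\t", index=False)
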