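"""Batch orchestration: screen, score, reliability and correlation runs.

The pipeline is deterministic: the same corpus, configuration and seed
produce byte-identical output tables. Every output carries provenance
metadata (lexicon name/version, a hash of the configuration, and the
screening bookkeeping: how many documents were excluded and why).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from .ev_metrics import Category, ev_score, score_document
from .inferential_stats import CorrelationResult, correlate
from .lexicon import (
    EmotionLexicon,
    NEGATIVE,
    POSITIVE,
    WordList,
    packaged_category,
    packaged_category_names,
    packaged_coverage_vocabulary,
    packaged_function_words,
    packaged_lexicon,
)
from .text_core import TokenizedDocument, screen_document, tokenize

__all__ = [
    "PipelineConfig",
    "CorpusScores",
    "Resources",
    "default_resources",
    "score_corpus",
    "split_half_reliability",
    "test_retest",
    "ev_metric",
]

log = logging.getLogger("emovocab")

Metric = Callable[[TokenizedDocument], float]


@dataclass(frozen=True)
class PipelineConfig:
    """Pinned analysis parameters; hashed into every output for provenance.

    ``preset("study1")`` keeps the default 2000 bootstrap replicates;
    ``preset("study2")`` lowers them to 500, the convention for very
    large samples where the bootstrap is expensive.
    """

    min_tokens: int = 100
    min_coverage: float = 0.70
    n_boot: int = 2000
    seed: int = 0
    rescreen_halves: bool = True
    split_unit: str = "token"           # "token" (midpoint of token stream)
    lexicon_path: Optional[str] = None
    function_words_path: Optional[str] = None
    coverage_path: Optional[str] = None
    category_paths: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def preset(cls, name: str, **overrides) -> "PipelineConfig":
        presets = {"study1": {"n_boot": 2000}, "study2": {"n_boot": 500}}
        if name not in presets:
            raise ValueError(f"unknown preset {name!r}")
        return cls(**{**presets[name], **overrides})

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**raw)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8")

    @property
    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class Resources:
    """The dictionary and word lists a scoring run operates with."""

    lexicon: EmotionLexicon
    function_words: WordList
    coverage_vocab: WordList
    categories: Mapping[str, Category]


def default_resources(config: Optional[PipelineConfig] = None) -> Resources:
    """Packaged lexicon/word lists, overridable through config paths.

    The configured categories are the packaged demo lists plus frequency-
    based emotional tone (``neg_tone``/``pos_tone``), computed as the
    valence slices of the emotion lexicon with repetition counted.
    """
    from .lexicon import load_lexicon, load_wordlist

    config = config or PipelineConfig()
    lexicon = (load_lexicon(config.lexicon_path)
               if config.lexicon_path else packaged_lexicon())
    function_words = (
        load_wordlist(config.function_words_path, role="function_words")
        if config.function_words_path else packaged_function_words())
    coverage = (
        load_wordlist(config.coverage_path, role="coverage_vocabulary")
        if config.coverage_path else packaged_coverage_vocabulary())
    categories: dict[str, Category] = {
        "neg_tone": lexicon.slice(NEGATIVE),
        "pos_tone": lexicon.slice(POSITIVE),
    }
    if config.category_paths:
        for name, p in config.category_paths.items():
            categories[name] = load_wordlist(p, role="category", name=name)
    else:
        for name in packaged_category_names():
            categories[name] = packaged_category(name)
    return Resources(lexicon=lexicon, function_words=function_words,
                     coverage_vocab=coverage, categories=categories)


@dataclass(frozen=True)
class CorpusScores:
    """Scored corpus: one row per included document, plus bookkeeping."""

    scores: pd.DataFrame          # doc_id, token_count, metrics, covariates
    exclusions: pd.DataFrame      # doc_id, token_count, coverage, reasons
    metadata: Mapping[str, object]

    @property
    def n_included(self) -> int:
        return len(self.scores)

    @property
    def n_excluded(self) -> int:
        return len(self.exclusions)

    def write(self, path: Union[str, Path]) -> None:
        path = Path(path)
        with path.open("w", encoding="utf-8", newline="") as fh:
            for k, v in self.metadata.items():
                fh.write(f"# {k}: {v}\n")
            self.scores.to_csv(fh, sep="\t", index=False)


def _tokenize_corpus(corpus: pd.DataFrame) -> tuple[
        list[TokenizedDocument], list[dict], int]:
    """Tokenize rows, logging and skipping unreadable ones."""
    docs, bad = [], 0
    rows = []
    for rec in corpus.to_dict("records"):
        text = rec.get("text")
        if not isinstance(text, str):
            log.warning("skipping unreadable row doc_id=%r", rec.get("doc_id"))
            bad += 1
            continue
        docs.append(tokenize(text, doc_id=str(rec["doc_id"])))
        rows.append(rec)
    return docs, rows, bad


def score_corpus(corpus: pd.DataFrame, resources: Optional[Resources] = None,
                 config: Optional[PipelineConfig] = None) -> CorpusScores:
    """Screen then score every document of a corpus table.

    ``corpus`` needs ``doc_id`` and ``text`` columns; other columns are
    carried through as covariates on the score rows. Excluded documents
    are recorded once each, with reasons, in the exclusion log. Raises if
    the corpus is empty or every row is screened out.
    """
    config = config or PipelineConfig()
    resources = resources or default_resources(config)
    if corpus is None or len(corpus) == 0:
        raise ValueError("empty corpus")

    docs, rows, n_unreadable = _tokenize_corpus(corpus)
    covar_cols = [c for c in corpus.columns if c not in ("doc_id", "text")]

    score_rows, excl_rows = [], []
    for doc, rec in zip(docs, rows):
        sr = screen_document(doc, resources.coverage_vocab,
                             min_tokens=config.min_tokens,
                             min_coverage=config.min_coverage)
        if not sr.included:
            excl_rows.append({
                "doc_id": doc.doc_id, "token_count": sr.token_count,
                "coverage": sr.coverage, "reasons": ";".join(sr.reasons),
            })
            continue
        row = score_document(doc, resources.lexicon,
                             resources.function_words, resources.categories)
        for c in covar_cols:
            row[c] = rec[c]
        score_rows.append(row)

    if not score_rows:
        raise ValueError("all documents were excluded by screening")
    scores = pd.DataFrame(score_rows)
    exclusions = pd.DataFrame(
        excl_rows, columns=["doc_id", "token_count", "coverage", "reasons"])
    log.info(
        "of the %d documents supplied, %d produced analyzable texts "
        "(%d excluded, %d unreadable)",
        len(corpus), len(scores), len(exclusions), n_unreadable)
    metadata = {
        "lexicon": f"{resources.lexicon.name} v{resources.lexicon.version}",
        "config_hash": config.config_hash,
        "n_input": len(corpus),
        "n_included": len(scores),
        "n_excluded": len(exclusions),
        "n_unreadable": n_unreadable,
    }
    return CorpusScores(scores=scores, exclusions=exclusions,
                        metadata=metadata)


def ev_metric(lexicon: EmotionLexicon, valence: str = NEGATIVE) -> Metric:
    """A per-document metric closure: the EV rate for one valence."""
    def metric(doc: TokenizedDocument) -> float:
        return ev_score(doc, lexicon, valence)
    return metric


def split_half_reliability(corpus: pd.DataFrame, metric: Metric,
                           resources: Optional[Resources] = None,
                           config: Optional[PipelineConfig] = None,
                           ) -> CorrelationResult:
    """Split each document's token stream at its midpoint, compute the
    metric on each half, and correlate half-1 with half-2 across
    documents (Pearson r with bootstrap SE and BCa CI).

    Documents are screened on the whole text first; by default each half
    is then re-screened against ``min_tokens`` (so a document needs at
    least ``2 * min_tokens`` tokens), switchable off via
    ``config.rescreen_halves``.
    """
    config = config or PipelineConfig()
    resources = resources or default_resources(config)
    docs, _, _ = _tokenize_corpus(corpus)

    pairs = []
    for doc in docs:
        sr = screen_document(doc, resources.coverage_vocab,
                             min_tokens=config.min_tokens,
                             min_coverage=config.min_coverage)
        if not sr.included:
            continue
        mid = doc.token_count // 2
        h1 = TokenizedDocument(doc.doc_id + "/h1", doc.tokens[:mid])
        h2 = TokenizedDocument(doc.doc_id + "/h2", doc.tokens[mid:])
        if config.rescreen_halves and (
                h1.token_count < config.min_tokens
                or h2.token_count < config.min_tokens):
            log.info("half of %s below %d tokens; skipped",
                     doc.doc_id, config.min_tokens)
            continue
        if h1.token_count == 0 or h2.token_count == 0:
            continue
        pairs.append({"doc_id": doc.doc_id,
                      "half1": metric(h1), "half2": metric(h2)})
    if len(pairs) < 3:
        raise ValueError(
            f"need >= 3 eligible documents, have {len(pairs)}")
    table = pd.DataFrame(pairs)
    return correlate(table, "half1", "half2",
                     n_boot=config.n_boot, seed=config.seed)


def test_retest(scores_t1: CorpusScores, scores_t2: CorpusScores,
                metric: str, config: Optional[PipelineConfig] = None,
                ) -> CorrelationResult:
    """Correlate a score column across two waves, joined on doc_id.

    Unmatched ids are logged; fewer than 3 matched pairs (or no overlap)
    is an error.
    """
    config = config or PipelineConfig()
    t1 = scores_t1.scores[["doc_id", metric]].rename(columns={metric: "t1"})
    t2 = scores_t2.scores[["doc_id", metric]].rename(columns={metric: "t2"})
    merged = t1.merge(t2, on="doc_id", how="inner")
    unmatched = (set(t1.doc_id) | set(t2.doc_id)) - set(merged.doc_id)
    if unmatched:
        log.info("%d unmatched ids across waves (e.g. %s)",
                 len(unmatched), sorted(unmatched)[:3])
    if len(merged) < 3:
        raise ValueError(
            f"need >= 3 matched pairs across waves, have {len(merged)}")
    return correlate(merged, "t1", "t2",
                     n_boot=config.n_boot, seed=config.seed)
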