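# emovocab

Quantify **active emotion vocabularies** in natural text.

Most word-count approaches to emotion language are *frequency*-based: a
text repeating "sad" ten times scores the same as a text using ten
different sadness words. `emovocab` implements the complementary
*diversity*-based index — the **emotion vocabulary (EV)** rate:

```
EV = (# unique emotion words / total word count) × 100
```

where "unique" is counted at the lemma level (*sad*, *sadness*, *sadly*
are one emotion word), against a closed dictionary of words that
primarily *name* emotional states, split into negative families
(sadness, anxiety/fear, anger, undifferentiated negative) and positive
words. The clause *"he was so angry at me, but sadly there was nothing I
could do"* has 14 words and two unique negative emotion words (*angry*;
*sadly* → *sad*), so its negative EV is 2/14 × 100 = **14.29**.

The package is aimed at researchers in computational psycholinguistics
and mental-health text analysis who want to relate emotion-word
diversity to well-being measures. Around the core index it provides:

- a validated dictionary format (literal tokens, prefix-wildcard stems,
  explicit lemma groups) with a packaged demonstration lexicon of
  92 negative and 53 positive emotion-word lemmas;
- tokenization and analyzability screening (≥ 100 words, ≥ 70% of words
  identifiable against a common vocabulary);
- frequency-based category rates (emotional tone, cognitive processing,
  I-words, we-words, illness, affiliation, achievement, leisure) and a
  general-vocabulary type/token ratio restricted to open-class,
  non-emotion words;
- split-half and test–retest reliability, and Pearson / partial
  correlations with bootstrap standard errors and 95% bias-corrected and
  accelerated (BCa) confidence intervals;
- a synthetic-corpus generator with latent author parameters (active
  lexicon-subset sizes, Zipf-skewed word reuse, emission rates, linked
  covariates) so every pipeline stage is testable end to end.

## Worked example

```python
import emovocab as ev

lexicon = ev.packaged_lexicon()
doc = ev.tokenize("he was so angry at me, but sadly there was nothing "
                  "I could do", doc_id="example")
print(doc.token_count)                         # 14
print(round(ev.ev_score(doc, lexicon, "negative"), 2))   # 14.29
```

A fuller run (`python examples/reliability_and_correlations.py`)
simulates 300 authors whose latent negative-vocabulary size is linked to
a synthetic distress rating, then prints:

```
split-half reliability of negative EV: r = 0.423 (SE 0.070), 95% BCa CI [0.273, 0.558], n = 293, p = 3.7e-14 [pearson]
partial r(neg_ev, distress | vocab, tone): r = 0.280 (SE 0.049), 95% BCa CI [0.187, 0.370], n = 300, p = 9.8e-07 [partial | open_class_ttr, neg_tone, pos_tone]
```

The first line says EV behaves like a stable author trait (halves of the
same documents correlate across authors); the second recovers the
planted vocabulary–distress association after controlling for general
vocabulary (open-class TTR) and both emotional-tone rates — the planted
effect survives exactly the confounds the partialling is meant to
remove.

Other examples: `examples/score_a_document.py` (single-document scores),
`examples/screen_and_score_corpus.py` (batch scoring with exclusion
bookkeeping), `examples/simulate_corpus.py` (latent-truth simulation).

## Command line

```bash
emovocab simulate --n-authors 500 --seed 1 \
    --out-corpus corpus.tsv --out-truth truth.tsv
emovocab score --corpus corpus.tsv --out scores.tsv
emovocab reliability --corpus corpus.tsv --mode split-half --metric neg_ev
emovocab correlate --scores scores.tsv --x neg_ev --y distress \
    --controls open_class_ttr,neg_tone,pos_tone --preset study2
```

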