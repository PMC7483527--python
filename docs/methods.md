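# Methods

## The emotion-vocabulary index

`emovocab` measures the *diversity* of emotion word use. For a document
of `N` tokens in which `U` distinct emotion lemma groups of a given
valence occur, the emotion-vocabulary rate is

```
EV = 100 · U / N
```

i.e. unique emotion words per 100 tokens. Uniqueness is counted at the
**lemma-group** level: the dictionary maps every surface form (and
optional wildcard stem) to a lemma group, and *sad*, *sadness*, *sadly*
all belong to group `sad`, contributing 1 to `U` no matter how often or
in how many inflections they appear. Dividing by `N` removes the
mechanical dependence of unique-word counts on text length, though the
expected EV of a fixed author still declines slowly with length because
the numerator saturates at the author's active repertoire while the
denominator keeps growing — which is why reliability analyses compare
documents of broadly similar length.

Family-specific EVs apply the same formula restricted to one family:
`sadness`, `fear`, `anger`, `undifferentiated_negative` (general
negative state words such as *awful*, *terrible*, *bad*) and `positive`.
Negative families partition the negative lemma groups, so family unique
counts add up to the negative unique count exactly.

Frequency-based **category rates** are the classic closed-vocabulary
counting convention kept for comparison and as control variables:
100 · (matching tokens, repeats included) / N. Emotional tone
(`neg_tone`, `pos_tone`) is computed this way over the valence slices of
the emotion lexicon; the other packaged categories (cognitive
processing, I-words, we-words, illness, affiliation, achievement,
leisure) are flat word lists. The category machinery is list-agnostic;
the packaged lists are labelled demonstration stand-ins, since widely
used commercial category dictionaries cannot be redistributed.

**General vocabulary** is a type/token ratio (TTR), reported raw
(100 · types / tokens) and in the open-class variant that removes
function words and *all* emotion-lexicon matches from numerator and
denominator before counting. The open-class variant is the one meant to
serve as a verbal-ability control in correlations: excluding emotion
words keeps the control variable from sharing tokens with the EV
numerator it is controlling for. (The classic "A horse! A horse! My
Kingdom for a horse!" illustration — 5 types over 9 tokens, 55.56 — is a
*raw* TTR; both variants are exposed.)

## Dictionary format and matching

Dictionaries are UTF-8 TSV (`pattern valence family lemma_group`,
`#` comments allowed). Patterns are literal lowercase tokens or
prefix-wildcard stems with one trailing `*`. Matching is deterministic:
literal entries beat wildcards; among matching wildcards the longest
prefix wins; each pattern may carry exactly one valence and family, and
conflicts (duplicate patterns, lemma groups spanning families) are
load-time errors, never match-time tie-breaks. Lemma collapsing is
explicit in the file rather than produced by a stemmer, so the mapping
is auditable and reproducible.

The packaged lexicon contains exactly **92 negative and 53 positive
lemma headwords**; the convention adopted (and asserted in tests) is
that the headline counts refer to lemma groups, with inflected surface
forms and wildcard stems as additional rows inside those groups. Every
group retains at least one literal surface form so the generator can
emit from any group.

## Tokenization and screening

Tokens are maximal runs of letters optionally joined by internal
apostrophes after NFC normalization, curly-apostrophe folding and
lowercasing; hyphenated compounds split (maximizing dictionary matches),
digit-only strings drop, and contractions stay whole. The two worked
examples above pin this convention (14 and 9 tokens).

A document is analyzable when it has ≥ `min_tokens` (default 100) tokens
and ≥ `min_coverage` (default 0.70) of them appear in a coverage
vocabulary — a packaged common-English list standing in for the
proprietary default lexicon of commercial tools, swappable via
configuration. Exclusions are logged once each with every failed
criterion.

## Reliability

*Split-half*: each document's token stream is cut at the midpoint, the
metric computed per half, and halves correlated across authors. By
default each half is re-screened against `min_tokens` (so a document
needs ≥ 2·`min_tokens` tokens); `rescreen_halves=False` disables this
for corpora of shorter texts. *Test–retest*: a score column is joined on
document/author id across two waves and correlated; unmatched ids are
logged.

## Correlation machinery

Pearson estimates come from the standard product-moment formula; partial
correlations are the Pearson correlation of the residuals of x and y
after least-squares projection on the controls plus an intercept
(with zero controls the two coincide exactly). Missing data are dropped
listwise per reported correlation. Two-tailed p-values use the t
transformation of r with `n − 2 − #controls` degrees of freedom,
reported alongside the bootstrap interval.

Uncertainty is bootstrap-based, resampling authors (rows) with
replacement, without stratification:

- SE = standard deviation of the bootstrap replicates;
- 95% BCa interval with bias-correction `z0 = Φ⁻¹(fraction of
  replicates below the point estimate)` — ties counted half, and the
  fraction clipped to `[1/(2B), 1 − 1/(2B)]` so `z0` stays finite on
  heavily tied distributions — and acceleration from the standard
  jackknife skewness formula `a = Σd³ / (6(Σd²)^{3/2})`, `d` being the
  deviations of leave-one-out statistics from their mean (the exact
  jackknife variant is a documented choice; nothing downstream is
  sensitive to it at these sample sizes);
- interval endpoints are order statistics of the bootstrap distribution
  (no interpolation);
- resamples on which the statistic is undefined are re-drawn and
  counted; more than 1% of `n_boot` re-draws is an error;
- everything is deterministic given the seed.

Default `n_boot` is 2000 (`preset("study1")`); `preset("study2")` uses
500, the convention for very large samples. Simulation tests check the
interval's empirical coverage for r at n = 200 (nominal 95%, observed
within [0.92, 0.975] over 1000 repeats) and its agreement with an
independent BCa implementation.

## Synthetic corpus generator

The generator emulates the statistical structure the analyses assume,
not natural language. Each author draws:

| parameter | default | meaning |
| --- | --- | --- |
| `k_neg`, `k_pos` | uniform int 1–15 | active-subset sizes: how many negative/positive lemma groups the author ever uses |
| `p_emit_neg`, `p_emit_pos` | 0.024 / 0.036 | per-token probability of emitting an emotion word (≈ the 2.4% / 3.6% tone rates typical of introspective writing), with a ±25% per-author multiplicative jitter |
| `verbosity` | Normal(600, 200), min 120 | target token count, matching stream-of-consciousness-essay scale |
| `zipf_s` | 1.0 | within-subset reuse skew: group i of the subset is drawn ∝ i⁻ˢ (principle-of-least-effort reuse) |
| covariate links | `distress = 0.3·z(k_neg) + N(0,1)`, `wellbeing = 0.3·z(k_pos) + N(0,1)` | planted linear associations between latent diversity and observed covariates |

Token-by-token, a position becomes a negative emotion word with
probability `p_emit_neg` (group Zipf-sampled from the author's subset,
inflection uniform among the group's literal surface forms), a positive
word likewise, and otherwise a filler word drawn from the coverage
vocabulary. Verbosity varies across authors so length normalization is
actually exercised. All randomness flows from one seeded generator and
the seed is recorded in output metadata.

The defaults were anchored to the descriptive scale of naturalistic
writing samples — tone rates of a few percent and roughly 3–4 unique
negative emotion words in a ~600-word text — so that simulated EV rates
land near 0.5–1 per 100 tokens. What the generator does **not** emulate:
syntax, topic structure, polysemy (every emitted emotion token is a true
emotion word, unlike real text where *alone* or *hurt* may not refer to
feelings), spelling variation, and any dependence between consecutive
tokens. Passing tests therefore demonstrate that the *pipeline*
recovers planted structure under the stated generative assumptions, not
that EV is valid for any particular real corpus.

## Numerical and design choices

- Rates are kept at full precision internally; comparisons to printed
  two-decimal values round at presentation time only.
- Empty documents are errors for every rate (the quantity is
  undefined), not zeros; an all-function-word document has its
  open-class TTR flagged as undefined rather than erroring.
- The midpoint split is by token index; entry-level splitting is left
  to configuration when entry boundaries exist in the input.
- `undifferentiated_negative` is an explicit family tag in the
  dictionary, not a residual bucket.
- Pipeline outputs embed the lexicon name/version and a SHA-256 hash of
  the configuration; identical corpus + config + seed reproduce outputs
  byte for byte (set iteration is avoided anywhere order could leak into
  output).
- Statistical near-zero assertions in tests use analytic sampling-error
  bounds (multiples of 1/√n) rather than ad hoc tolerances.

## Known limitations

- The packaged dictionary and category lists are demonstration
  reconstructions; substantive research should supply its own validated
  lists via the documented formats.
- EV scores of short documents are coarse (a 100-word text can only
  take EV values in steps of 1), which bounds attainable reliabilities.
- The tokenizer is English-oriented (apostrophe handling, function-word
  list); multilingual lexica are out of scope.
- No correction for multiple testing is applied; correlation reports
  are uncorrected two-tailed tests by design.
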