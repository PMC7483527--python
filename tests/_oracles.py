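"""Independent brute-force oracles, kept deliberately naive.

These re-implement every per-document metric and the partial correlation
as direct single-pass scans over the raw entry list / normal equations,
sharing no code with the library's implementations.
"""

import numpy as np


def oracle_match(entries, token):
    """Literal beats wildcard; longest wildcard prefix wins."""
    for e in entries:
        if not e.pattern.endswith("*") and e.pattern == token:
            return e
    best = None
    for e in entries:
        if e.pattern.endswith("*") and token.startswith(e.pattern[:-1]):
            if best is None or len(e.pattern) > len(best.pattern):
                best = e
    return best


def oracle_ev(tokens, entries, valence):
    groups = set()
    for t in tokens:
        e = oracle_match(entries, t)
        if e is not None and e.valence == valence:
            groups.add(e.lemma_group)
    return 100.0 * len(groups) / len(tokens)


def oracle_family_ev(tokens, entries, family):
    groups = set()
    for t in tokens:
        e = oracle_match(entries, t)
        if e is not None and e.family == family:
            groups.add(e.lemma_group)
    return 100.0 * len(groups) / len(tokens)


def oracle_wordlist_rate(tokens, words):
    hits = 0
    for t in tokens:
        if t in words:
            hits += 1
    return 100.0 * hits / len(tokens)


def oracle_lexicon_rate(tokens, entries):
    hits = 0
    for t in tokens:
        if oracle_match(entries, t) is not None:
            hits += 1
    return 100.0 * hits / len(tokens)


def oracle_raw_ttr(tokens):
    return 100.0 * len(set(tokens)) / len(tokens)


def oracle_open_class_ttr(tokens, function_words, entries):
    kept = [t for t in tokens
            if t not in function_words
            and oracle_match(entries, t) is None]
    if not kept:
        return None
    return 100.0 * len(set(kept)) / len(kept)


def oracle_partial_correlation(x, y, controls):
    """Residual correlation via explicit normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    c = np.asarray(controls, float)
    if c.ndim == 1:
        c = c[:, None]
    z = np.column_stack([np.ones(len(x)), c])
    bx = np.linalg.solve(z.T @ z, z.T @ x)
    by = np.linalg.solve(z.T @ z, z.T @ y)
    rx = x - z @ bx
    ry = y - z @ by
    return float(np.corrcoef(rx, ry)[0, 1])
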