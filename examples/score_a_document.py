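"""Score a single document: EV rates, family EVs, tone and TTR.

EV counts *unique* (lemma-collapsed) emotion words per 100 tokens, so a
writer who repeats "sad" ten times gets the same tone score but a much
lower EV than one who uses ten different sadness words.
"""

import emovocab as ev

text = ("I was so angry and frustrated yesterday, and today I just feel "
        "sad and hopeless about it. My roommate tried to help but I was "
        "too annoyed to listen. Writing this down makes me a bit calmer "
        "and honestly a little hopeful that tomorrow will be better.")

lexicon = ev.packaged_lexicon()
function_words = ev.packaged_function_words()

doc = ev.tokenize(text, doc_id="diary_entry")
scores = ev.score_ev(doc, lexicon)
ttr = ev.ttr(doc, function_words, lexicon)
neg_tone = ev.category_rate(doc, lexicon.slice("negative"))

print(f"tokens               : {doc.token_count}")
print(f"negative EV          : {scores.neg_ev:.2f}  "
      f"({scores.unique_neg} unique negative emotion words per "
      f"{doc.token_count} tokens, x100)")
print(f"positive EV          : {scores.pos_ev:.2f}")
for family, rate in scores.family_ev.items():
    print(f"  EV[{family:<26s}]: {rate:.2f}")
print(f"negative tone (freq) : {neg_tone:.2f}  (% of tokens, repeats count)")
print(f"raw TTR              : {ttr.raw_ttr:.2f}")
print(f"open-class TTR       : {ttr.open_class_ttr:.2f}  "
      f"(function + emotion words excluded)")
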